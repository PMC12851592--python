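"""Circular statistics and stratified permutation inference for orientation.

Ommatidial orientation angles (degrees relative to the eye equator) are
directional data on the full circle. Summaries are the circular mean
direction μ and the mean resultant length R ∈ [0, 1] (0 = uniform,
1 = perfect alignment). Two-sample inference uses Watson's U² — an
integrated squared difference of the circular empirical CDFs, sensitive to
both location and scale — or the absolute difference of per-group resultant
lengths. Because multiple ommatidia are measured per eye, the permutation
null shuffles genotype labels only *within* each eye, preserving the nested
sampling structure; p-values carry the small-sample correction
(k + 1)/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import OrientationDataset
from .errors import ValidationError

__all__ = [
    "CircularSummary",
    "PermutationResult",
    "circ_mean_resultant",
    "watson_u2",
    "stratified_permutation_test",
    "compare_resultant_lengths",
    "mirror_ventral_angles",
]


@dataclass(frozen=True)
class CircularSummary:
    """Circular mean direction and mean resultant length of a sample.

    ``mu_deg`` is None when R = 0 (direction undefined by antipodal
    cancellation or uniformity).
    """

    mu_deg: float | None
    R: float
    n: int

    @property
    def mu_defined(self) -> bool:
        return self.mu_deg is not None


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    p_value: float
    n_permutations: int
    statistic_kind: str  # "watson_u2" | "resultant_diff"


def circ_mean_resultant(angles_deg) -> CircularSummary:
    """Mean direction and resultant length via the unit-vector mean."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one angle")
    rad = np.radians(a)
    c, s = np.cos(rad).mean(), np.sin(rad).mean()
    R = float(np.hypot(c, s))
    if R < 1e-12:
        return CircularSummary(None, 0.0, a.size)
    mu = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return CircularSummary(mu, min(R, 1.0), a.size)


def watson_u2(sample_a, sample_b) -> float:
    """Two-sample Watson U² statistic.

    Over the combined circularly ordered sample of size N = n + m, with d_k
    the difference of the two empirical CDFs at the k-th point,

        U² = (n·m / N²) · Σ (d_k − d̄)²

    The centring on d̄ makes the statistic invariant to a common rotation of
    both samples and to swapping the sample labels. U² = 0 iff the ECDFs
    coincide at every combined point.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    N = n + m
    if N < 4:
        raise ValueError("combined sample size must be at least 4")
    combined = np.concatenate([np.mod(a, 360.0), np.mod(b, 360.0)])
    is_a = np.zeros(N, dtype=float)
    is_a[:n] = 1.0
    order = np.argsort(combined, kind="stable")
    z = is_a[order]
    d = np.cumsum(z) / n - np.cumsum(1.0 - z) / m
    # ties: both ECDFs jump together, so evaluate d at the end of each tie group
    d = d[_tie_group_ends(combined[order])]
    return float(n * m / N**2 * (np.sum(d**2) - np.sum(d) ** 2 / N))


def _tie_group_ends(sorted_values: np.ndarray) -> np.ndarray:
    """For each position in a sorted array, the index of its tie-group end."""
    N = sorted_values.size
    is_end = np.empty(N, dtype=bool)
    is_end[-1] = True
    is_end[:-1] = sorted_values[1:] != sorted_values[:-1]
    ends = np.nonzero(is_end)[0]
    sizes = np.diff(np.concatenate([[-1], ends]))
    return np.repeat(ends, sizes)


def mirror_ventral_angles(
    records: pd.DataFrame, side_col: str = "side", ventral_label: str = "ventral"
) -> pd.DataFrame:
    """Reflect ventral-eye angles into the dorsal frame (θ → 360 − θ).

    Dorsal and ventral ommatidia rotate in opposite senses about the
    equator; mirroring makes the two halves directly poolable. Tables
    without a ``side`` column are returned unchanged.
    """
    if side_col not in records.columns:
        return records
    df = records.copy()
    mask = df[side_col] == ventral_label
    df.loc[mask, "angle_deg"] = (360.0 - df.loc[mask, "angle_deg"]) % 360.0
    return df


# ---------------------------------------------------------------------------
# stratified permutation machinery


def _prepare_two_group(data: OrientationDataset):
    """Validate the two-genotype nested design; drop one-label eyes."""
    df = data.records
    genos = sorted(df["genotype"].unique().tolist())
    if len(genos) != 2:
        raise ValidationError(
            f"stratified test needs exactly two genotypes, found {genos}"
        )
    keep = []
    for eye, sub in df.groupby("eye_id", sort=True):
        if sub["genotype"].nunique() == 2:
            keep.append(sub)
        else:
            warnings.warn(
                f"eye {eye!r} lacks one genotype and is excluded from the "
                "stratified permutation test",
                stacklevel=3,
            )
    if not keep:
        raise ValidationError("no eye contains both genotypes")
    df = pd.concat(keep, ignore_index=True)
    angles = df["angle_deg"].to_numpy(dtype=float)
    labels = (df["genotype"] == genos[1]).to_numpy()  # False=group A, True=group B
    eye_codes = pd.factorize(df["eye_id"])[0]
    return angles, labels, eye_codes, genos


def _permuted_label_matrix(labels, eye_codes, n_perm, rng):
    """(n_perm, N) boolean matrix: labels shuffled independently within eyes."""
    n = labels.size
    Z = np.broadcast_to(labels, (n_perm, n)).copy()
    for eye in np.unique(eye_codes):
        idx = np.nonzero(eye_codes == eye)[0]
        keys = rng.random((n_perm, idx.size))
        order = np.argsort(keys, axis=1, kind="stable")
        Z[:, idx] = labels[idx][order]
    return Z


def _watson_u2_rows(angles, Z):
    """Vectorised Watson U² for each row of a label matrix Z (True = group B)."""
    n_b = int(Z[0].sum())
    n_a = Z.shape[1] - n_b
    N = Z.shape[1]
    order = np.argsort(angles, kind="stable")
    ends = _tie_group_ends(angles[order])
    zb = Z[:, order].astype(float)
    d = np.cumsum(1.0 - zb, axis=1) / n_a - np.cumsum(zb, axis=1) / n_b
    d = d[:, ends]
    return n_a * n_b / N**2 * (np.sum(d**2, axis=1) - np.sum(d, axis=1) ** 2 / N)


def _resultant_diff_rows(angles, Z):
    """Vectorised |R_A − R_B| for each row of a label matrix Z."""
    rad = np.radians(angles)
    c, s = np.cos(rad), np.sin(rad)
    zb = Z.astype(float)
    za = 1.0 - zb
    n_b = int(Z[0].sum())
    n_a = Z.shape[1] - n_b
    R_a = np.hypot(za @ c, za @ s) / n_a
    R_b = np.hypot(zb @ c, zb @ s) / n_b
    return np.abs(R_a - R_b)


_STAT_FUNCS = {"watson_u2": _watson_u2_rows, "resultant_diff": _resultant_diff_rows}


def stratified_permutation_test(
    data: OrientationDataset,
    statistic_kind: str = "watson_u2",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Two-genotype permutation test with eye-level stratification.

    The observed statistic is computed on the real labels; each of the
    ``n_permutations`` resamples shuffles genotype labels independently
    within every eye (per-eye group sizes are preserved exactly). With k the
    number of permuted statistics ≥ the observed value (ties counted,
    conservatively), p = (k + 1)/(n_permutations + 1), so the smallest
    attainable p is 1/(n_permutations + 1).
    """
    if statistic_kind not in _STAT_FUNCS:
        raise ValueError(f"unknown statistic_kind {statistic_kind!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    angles, labels, eye_codes, _ = _prepare_two_group(data)
    stat_rows = _STAT_FUNCS[statistic_kind]
    observed = float(stat_rows(angles, labels[None, :])[0])
    rng = np.random.default_rng(seed)
    Z = _permuted_label_matrix(labels, eye_codes, n_permutations, rng)
    null = stat_rows(angles, Z)
    k = int(np.count_nonzero(null >= observed - 1e-12))
    p = (k + 1) / (n_permutations + 1)
    return PermutationResult(observed, p, n_permutations, statistic_kind)


def compare_resultant_lengths(
    data: OrientationDataset, n_permutations: int = 10_000, seed: int = 0
) -> PermutationResult:
    """Stratified permutation test on |R_A − R_B| (angle-concentration contrast)."""
    return stratified_permutation_test(
        data, "resultant_diff", n_permutations, seed
    )
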