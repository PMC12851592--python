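"""Synthetic fixtures with the statistical structure the analyses assume.

The generators stand in for microscope-derived tables: quasi-ordered nipple
arrays (jittered hexagonal lattices), hard-core and Poisson null patterns,
nested von Mises orientation data, noisy hexagonal cornea outlines, and
three-trial phototaxis outcomes. Every generator takes an explicit seed and
is bitwise-reproducible; there is no global random state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import OrientationDataset, PhototaxisAssay, PointPattern, Window
from .errors import SaturationError

__all__ = [
    "gen_poisson_pattern",
    "gen_hardcore_pattern",
    "gen_jittered_hex_lattice",
    "gen_orientation_dataset",
    "gen_two_genotype_orientation",
    "gen_hexagon_polygon",
    "gen_phototaxis_counts",
]


def gen_poisson_pattern(
    n: int,
    window: Window,
    seed: int,
    eye_id: str = "eye0",
    genotype: str = "csr",
) -> PointPattern:
    """Binomial (conditional Poisson) pattern: n points uniform in the window.

    This is the complete-spatial-randomness reference against which observed
    nipple arrays are judged; its pair correlation is identically 1.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    xs = rng.uniform(window.x_min, window.x_max, size=n)
    ys = rng.uniform(window.y_min, window.y_max, size=n)
    return PointPattern(np.column_stack([xs, ys]), window, eye_id, genotype)


def gen_hardcore_pattern(
    n: int,
    window: Window,
    d_min: float,
    seed: int,
    max_attempts: int | None = None,
    eye_id: str = "eye0",
    genotype: str = "hardcore",
) -> PointPattern:
    """Random sequential adsorption: uniform proposals, rejected within d_min.

    Models points "placed randomly but constrained by a minimum separation",
    the null for nipple arrays whose only order is steric exclusion at the
    nipple diameter. Raises :class:`SaturationError` if n points cannot be
    placed within ``max_attempts`` proposals (default ``max(10_000, 500 n)``).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    disk_area = n * np.pi * (d_min / 2.0) ** 2
    if disk_area >= 0.5 * window.area:
        # RSA jams near packing fraction 0.547 in 2D; beyond half coverage
        # the request is hopeless and we fail fast.
        raise SaturationError(n, 0, 0)
    if max_attempts is None:
        max_attempts = max(10_000, 500 * n)
    rng = np.random.default_rng(seed)
    accepted = np.empty((n, 2), dtype=float)
    n_acc = 0
    d2 = d_min * d_min
    attempts = 0
    # cell grid with cell size d_min: a conflicting point can only sit in the
    # 3×3 neighbourhood of the proposal's cell
    cells: dict[tuple, list] = {}

    def cell_of(p):
        return (int((p[0] - window.x_min) // d_min), int((p[1] - window.y_min) // d_min))

    while n_acc < n:
        if attempts >= max_attempts:
            raise SaturationError(n, n_acc, max_attempts)
        batch = min(max_attempts - attempts, max(64, n - n_acc))
        props = np.column_stack(
            [
                rng.uniform(window.x_min, window.x_max, size=batch),
                rng.uniform(window.y_min, window.y_max, size=batch),
            ]
        )
        for p in props:
            attempts += 1
            cx, cy = cell_of(p)
            clash = False
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for idx in cells.get((cx + dx, cy + dy), ()):
                        q = accepted[idx]
                        if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < d2:
                            clash = True
                            break
                    if clash:
                        break
                if clash:
                    break
            if clash:
                continue
            accepted[n_acc] = p
            cells.setdefault((cx, cy), []).append(n_acc)
            n_acc += 1
            if n_acc == n:
                break
    return PointPattern(accepted[:n], window, eye_id, genotype)


def gen_jittered_hex_lattice(
    spacing: float,
    jitter_sd: float,
    window: Window,
    seed: int,
    eye_id: str = "eye0",
    genotype: str = "ordered",
) -> PointPattern:
    """Hexagonal lattice with isotropic Gaussian positional jitter.

    Emulates the wild-type quasi-ordered nipple array: short-range order with
    a first pair-correlation peak near ``spacing`` that washes out as
    ``jitter_sd`` grows. Jittered points falling outside the window are
    discarded, as in a cropped SEM field.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    dy = spacing * np.sqrt(3.0) / 2.0
    margin = 4.0 * jitter_sd + spacing
    rows = np.arange(window.y_min - margin, window.y_max + margin + dy, dy)
    pts = []
    for i, y in enumerate(rows):
        x_off = 0.5 * spacing if i % 2 else 0.0
        xs = np.arange(
            window.x_min - margin + x_off, window.x_max + margin + spacing, spacing
        )
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    lattice = np.vstack(pts)
    if jitter_sd > 0:
        lattice = lattice + rng.normal(0.0, jitter_sd, size=lattice.shape)
    lattice = lattice[
        (lattice[:, 0] >= window.x_min)
        & (lattice[:, 0] <= window.x_max)
        & (lattice[:, 1] >= window.y_min)
        & (lattice[:, 1] <= window.y_max)
    ]
    return PointPattern(lattice, window, eye_id, genotype)


def gen_orientation_dataset(
    n_eyes: int,
    n_per_eye: int,
    mu_deg: float,
    kappa: float,
    genotype: str,
    seed: int,
    eye_prefix: str = "eye",
) -> OrientationDataset:
    """Nested von Mises angles: ``n_eyes`` strata × ``n_per_eye`` ommatidia.

    kappa = 0 gives circular-uniform angles; large kappa concentrates tightly
    around ``mu_deg``. The study design this emulates is eight eyes per
    genotype with five ommatidia measured per eye.
    """
    if n_eyes < 1 or n_per_eye < 1:
        raise ValueError("n_eyes and n_per_eye must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = np.random.default_rng(seed)
    total = n_eyes * n_per_eye
    angles = np.degrees(rng.vonmises(np.radians(mu_deg), kappa, size=total))
    records = pd.DataFrame(
        {
            "eye_id": [f"{eye_prefix}{i}" for i in range(n_eyes) for _ in range(n_per_eye)],
            "ommatidium_id": [
                f"{genotype}_om{i}_{j}" for i in range(n_eyes) for j in range(n_per_eye)
            ],
            "genotype": genotype,
            "angle_deg": np.mod(angles, 360.0),
        }
    )
    return OrientationDataset(records)


def gen_two_genotype_orientation(
    n_eyes: int,
    n_per_eye: int,
    mu_a: float,
    kappa_a: float,
    mu_b: float,
    kappa_b: float,
    seed: int,
    label_a: str = "control",
    label_b: str = "mutant",
) -> OrientationDataset:
    """Two genotypes measured in the same eyes (mosaic-clone design).

    Each eye contributes ``n_per_eye`` ommatidia of each genotype, so the
    stratified permutation test has both labels in every stratum.
    """
    rng = np.random.default_rng(seed)
    a = gen_orientation_dataset(
        n_eyes, n_per_eye, mu_a, kappa_a, label_a, int(rng.integers(2**31))
    )
    b = gen_orientation_dataset(
        n_eyes, n_per_eye, mu_b, kappa_b, label_b, int(rng.integers(2**31))
    )
    return a.concat(b)


def gen_hexagon_polygon(
    side: float, vertex_noise_sd: float, seed: int
) -> np.ndarray:
    """Regular hexagon (counter-clockwise, first vertex on +x axis) with
    isotropic Gaussian vertex noise; returns a (6, 2) vertex array in μm.

    Noise 0 gives the ideal cornea outline with circularity π√3/6 ≈ 0.907.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    if vertex_noise_sd < 0:
        raise ValueError("vertex_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    theta = np.arange(6) * np.pi / 3.0
    verts = side * np.column_stack([np.cos(theta), np.sin(theta)])
    if vertex_noise_sd > 0:
        verts = verts + rng.normal(0.0, vertex_noise_sd, size=verts.shape)
    return verts


def gen_phototaxis_counts(
    n_flies: int,
    p_trial: float,
    seed: int,
    assay_id: str = "assay0",
    genotype: str = "control",
    sex: str = "mixed",
) -> PhototaxisAssay:
    """Simulate one countercurrent assay under independent trials.

    Each fly passes each of the 3 consecutive light trials with probability
    ``p_trial``; tube k collects flies with exactly k passes, so tube counts
    are multinomial with Binomial(3, p) cell probabilities.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    if not 0.0 <= p_trial <= 1.0:
        raise ValueError("p_trial must be in [0, 1]")
    rng = np.random.default_rng(seed)
    successes = rng.binomial(3, p_trial, size=n_flies)
    counts = np.bincount(successes, minlength=4)
    return PhototaxisAssay(assay_id, genotype, sex, tuple(int(c) for c in counts))
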