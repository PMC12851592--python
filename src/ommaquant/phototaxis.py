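"""Countercurrent (Benzer-style) phototaxis scoring.

Dark-adapted flies get three consecutive one-minute chances to walk toward
a light source; tube k collects flies that responded k times. The reported
score of an assay is the final-tube fraction — the proportion of flies that
responded all three times (≈ 50% in healthy controls). Under an
independent-trials model with per-trial success probability p, the expected
final-tube fraction is p³, which the simulator in :mod:`ommaquant.synthetic`
reproduces; this model is a testing fixture, not a biological claim.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import PhototaxisAssay
from .errors import ValidationError

__all__ = ["score_assay", "expected_final_fraction", "summarize_by_group", "assays_to_frame"]


def score_assay(assay: PhototaxisAssay) -> float:
    """Final-tube fraction: flies responding three times / total flies."""
    if assay.n_total < 1:
        raise ValueError("assay has no flies")
    return assay.tube_counts[3] / assay.n_total


def expected_final_fraction(p_trial: float) -> float:
    """Expected final-tube fraction p³ under independent trials."""
    if not 0.0 <= p_trial <= 1.0:
        raise ValueError("p_trial must be in [0, 1]")
    return p_trial**3


def assays_to_frame(assays) -> pd.DataFrame:
    """Tabulate assays as one row each with their scored fraction."""
    rows = []
    for a in assays:
        rows.append(
            {
                "assay_id": a.assay_id,
                "genotype": a.genotype,
                "sex": a.sex,
                "n_total": a.n_total,
                "tube0": a.tube_counts[0],
                "tube1": a.tube_counts[1],
                "tube2": a.tube_counts[2],
                "tube3": a.tube_counts[3],
                "fraction": score_assay(a),
            }
        )
    return pd.DataFrame(rows)


def summarize_by_group(assays, group_keys=("genotype",)) -> pd.DataFrame:
    """Per-group mean, SD and count of scored final-tube fractions.

    ``group_keys`` selects grouping columns (any of genotype, sex). Groups
    with a single assay report SD as NaN (absent); empty inputs raise.
    """
    group_keys = list(group_keys)
    allowed = {"genotype", "sex", "assay_id"}
    bad = set(group_keys) - allowed
    if bad:
        raise ValidationError(f"unknown group keys: {sorted(bad)}")
    df = assays_to_frame(assays)
    if df.empty:
        raise ValueError("no assays to summarise")
    empty = df.groupby(group_keys)["fraction"].count() == 0
    if empty.any():  # pragma: no cover - groupby drops empty groups already
        warnings.warn("empty groups excluded from summary")
    out = (
        df.groupby(group_keys)["fraction"]
        .agg(mean_fraction="mean", sd=lambda s: s.std(ddof=1), n_assays="count")
        .reset_index()
    )
    out["sd"] = out["sd"].astype(float)
    return out
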