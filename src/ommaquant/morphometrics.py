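"""Shape, size and tally descriptors for corneas, nipples and bristles.

Shapes arrive as polygon vertex lists in μm (segmentation happens upstream,
in an image tool); descriptors are computed on the exact polygon geometry.
Circularity is 4πA/P²: 1 for a circle, π√3/6 ≈ 0.907 for a regular hexagon
(the reference value for a healthy cornea), lower for irregular outlines.
Length measurements made in pixels are converted to μm with a fiduciary
microsphere calibration; size distributions are compared with the
two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from shapely.geometry import Polygon

from .errors import GeometryError, ValidationError

__all__ = [
    "ShapeDescriptors",
    "Calibration",
    "BristleTally",
    "polygon_descriptors",
    "calibrate_lengths",
    "tally_bristles",
    "compare_distributions_ks",
    "BRISTLE_CLASSES",
]

BRISTLE_CLASSES = ("normal", "paintbrush", "duplicated", "triplicated", "quadruplicated")

#: combined-sample size at or below which the KS p-value is computed exactly
KS_EXACT_MAX_N = 50


@dataclass(frozen=True)
class ShapeDescriptors:
    area: float  # μm²
    perimeter: float  # μm
    circularity: float  # 4πA/P², dimensionless in (0, 1]
    equivalent_diameter: float  # μm, diameter of the equal-area circle


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-μm scale from fiduciary beads of known diameter.

    ``scale`` = nominal diameter (μm) / measured diameter (pixels). With
    several beads in one frame, use :meth:`from_beads` which averages the
    per-bead scales.
    """

    nominal_diameter: float  # μm
    measured_diameter: float  # pixels
    source: str = "fiduciary-microsphere"

    def __post_init__(self):
        if self.nominal_diameter <= 0 or self.measured_diameter <= 0:
            raise ValueError("calibration diameters must be positive")

    @property
    def scale(self) -> float:
        """μm per pixel."""
        return self.nominal_diameter / self.measured_diameter

    @classmethod
    def from_beads(cls, nominal_diameter: float, measured_px) -> "Calibration":
        """Average calibration over several beads measured in one frame."""
        px = np.asarray(measured_px, dtype=float)
        if px.size == 0 or (px <= 0).any():
            raise ValueError("bead measurements must be positive and non-empty")
        mean_scale = float(np.mean(nominal_diameter / px))
        # store as an equivalent single measurement so .scale is the mean scale
        return cls(nominal_diameter, nominal_diameter / mean_scale)


@dataclass(frozen=True)
class BristleTally:
    per_eye: pd.DataFrame  # one row per eye, one column per class
    pooled: dict  # class -> total count
    high_order_fraction_pct: float | None  # (tri+quad)/(dup+tri+quad) · 100
    per_eye_multiple_fraction: pd.Series  # (dup+tri+quad)/total per eye


def polygon_descriptors(vertices) -> ShapeDescriptors:
    """Area, perimeter, circularity and equivalent diameter of a polygon.

    The polygon must be simple (non-self-intersecting) and non-degenerate;
    vertex order (CW/CCW) does not matter.
    """
    verts = np.asarray(vertices, dtype=float).reshape(-1, 2)
    if verts.shape[0] < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise GeometryError("polygon is self-intersecting or otherwise invalid")
    area = float(poly.area)
    perimeter = float(poly.length)
    if area <= 0 or perimeter <= 0:
        raise GeometryError("degenerate polygon (zero area or perimeter)")
    circ = 4.0 * np.pi * area / perimeter**2
    return ShapeDescriptors(area, perimeter, circ, 2.0 * np.sqrt(area / np.pi))


def calibrate_lengths(measurements_px, cal: Calibration) -> np.ndarray:
    """Convert pixel lengths to μm using a bead calibration (linear scale)."""
    m = np.asarray(measurements_px, dtype=float)
    if (m <= 0).any():
        raise ValueError("measurements must be positive")
    return m * cal.scale


def tally_bristles(records: pd.DataFrame) -> BristleTally:
    """Count bristle phenotype classes per eye and pooled.

    ``records`` needs columns ``eye_id`` and ``class`` (one row per bristle;
    labels from the fixed vocabulary). The headline derived quantity is the
    percentage of triplicated-or-more bristles among all multiplied
    (duplicated + triplicated + quadruplicated) bristles; it is reported as
    None — absent, not zero — when no multiplied bristles exist.
    """
    for col in ("eye_id", "class"):
        if col not in records.columns:
            raise ValidationError(f"bristle table missing column {col!r}")
    bad = set(records["class"].unique()) - set(BRISTLE_CLASSES)
    if bad:
        raise ValidationError(f"unknown bristle class labels: {sorted(bad)}")
    per_eye = (
        records.groupby("eye_id")["class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(BRISTLE_CLASSES), fill_value=0)
    )
    pooled = {c: int(per_eye[c].sum()) for c in BRISTLE_CLASSES}
    multiple = pooled["duplicated"] + pooled["triplicated"] + pooled["quadruplicated"]
    high = pooled["triplicated"] + pooled["quadruplicated"]
    frac = 100.0 * high / multiple if multiple > 0 else None
    totals = per_eye.sum(axis=1)
    per_eye_multiple = (
        per_eye[["duplicated", "triplicated", "quadruplicated"]].sum(axis=1) / totals
    )
    return BristleTally(per_eye, pooled, frac, per_eye_multiple)


def compare_distributions_ks(values_a, values_b):
    """Two-sample two-sided Kolmogorov–Smirnov test on size distributions.

    Exact p-value for combined n ≤ 50 (the study's per-eye samples are
    small), asymptotic otherwise. Returns (statistic, p_value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if a.size + b.size <= KS_EXACT_MAX_N else "asymp"
    res = ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)
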