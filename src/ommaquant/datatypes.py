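"""Core containers shared across the analysis modules.

Lengths are in micrometres (μm) throughout; angles are degrees on the full
circle [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Window",
    "PointPattern",
    "OrientationDataset",
    "PhototaxisAssay",
]

ORIENTATION_COLUMNS = ["eye_id", "ommatidium_id", "genotype", "angle_deg"]


@dataclass(frozen=True)
class Window:
    """Rectangular observation window, axis-aligned, in μm."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("window must have positive extent on both axes")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of rows of an (n, 2) array lying inside the window."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (
            (pts[:, 0] >= self.x_min)
            & (pts[:, 0] <= self.x_max)
            & (pts[:, 1] >= self.y_min)
            & (pts[:, 1] <= self.y_max)
        )

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "x_max": self.x_max,
            "y_min": self.y_min,
            "y_max": self.y_max,
        }


@dataclass(frozen=True)
class PointPattern:
    """2D point pattern (e.g. corneal-nipple centroids) in a window.

    Parameters
    ----------
    points : (n, 2) array of float, μm
    window : Window
    eye_id : identifier of the source eye / field
    genotype : group label (e.g. ``"control"``, ``"mutant"``)
    """

    points: np.ndarray
    window: Window
    eye_id: str = "eye0"
    genotype: str = "unlabelled"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if pts.shape[0] and not self.window.contains(pts).all():
            raise ValueError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def density(self) -> float:
        """Intensity ρ in points per μm²."""
        return self.n / self.window.area


class OrientationDataset:
    """Nested ommatidial-orientation records (eye → ommatidium → angle).

    Thin wrapper over a DataFrame with columns
    ``eye_id, ommatidium_id, genotype, angle_deg``; angles are normalised to
    [0, 360) and each (eye_id, ommatidium_id) pair must be unique.
    """

    def __init__(self, records: pd.DataFrame):
        df = pd.DataFrame(records).copy()
        missing = [c for c in ORIENTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"orientation table missing columns: {missing}")
        df["angle_deg"] = np.mod(df["angle_deg"].astype(float), 360.0)
        if df.duplicated(subset=["eye_id", "ommatidium_id"]).any():
            raise ValidationError("duplicate (eye_id, ommatidium_id) records")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genotypes(self) -> list:
        return sorted(self.records["genotype"].unique().tolist())

    def angles(self, genotype: str | None = None) -> np.ndarray:
        df = self.records
        if genotype is not None:
            df = df[df["genotype"] == genotype]
        return df["angle_deg"].to_numpy(dtype=float)

    def concat(self, other: "OrientationDataset") -> "OrientationDataset":
        return OrientationDataset(
            pd.concat([self.records, other.records], ignore_index=True)
        )


@dataclass
class PhototaxisAssay:
    """One countercurrent run: counts of flies by number of light approaches.

    ``tube_counts[k]`` is the number of flies that moved toward the light in
    exactly k of the three trials; tube 3 holds the full responders that the
    assay reports.
    """

    assay_id: str
    genotype: str
    sex: str
    tube_counts: tuple = field(default=(0, 0, 0, 0))

    def __post_init__(self):
        counts = tuple(int(c) for c in self.tube_counts)
        if len(counts) != 4:
            raise ValidationError("tube_counts must have exactly 4 entries")
        if any(c < 0 for c in counts):
            raise ValidationError("tube counts must be non-negative")
        self.tube_counts = counts

    @property
    def n_total(self) -> int:
        return sum(self.tube_counts)
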