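"""Readers and writers for the package's tabular and JSON interchange formats.

All tables are UTF-8 CSV with a header row; structured outputs are JSON.
Point patterns travel as a coordinate CSV plus a sidecar window JSON; RDF
curves as CSV with ``#``-prefixed metadata header lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ORIENTATION_COLUMNS, OrientationDataset, PhototaxisAssay, PointPattern, Window
from .errors import ValidationError
from .rdf import RDFCurve

__all__ = [
    "write_point_patterns",
    "read_point_patterns",
    "write_window",
    "read_window",
    "write_orientation",
    "read_orientation",
    "write_assays",
    "read_assays",
    "write_rdf_curve",
    "read_rdf_curve",
    "write_json",
    "read_shapes",
    "write_shapes",
]


def write_window(window: Window, path) -> None:
    Path(path).write_text(json.dumps(window.to_dict(), indent=2) + "\n")


def read_window(path) -> Window:
    return Window(**json.loads(Path(path).read_text()))


def write_point_patterns(patterns, points_path, window_path=None) -> None:
    """Write one or more patterns to a coordinate CSV (+ sidecar window JSON).

    Patterns written together must share one observation window.
    """
    if isinstance(patterns, PointPattern):
        patterns = [patterns]
    frames = [
        pd.DataFrame(
            {
                "eye_id": p.eye_id,
                "genotype": p.genotype,
                "x_um": p.points[:, 0],
                "y_um": p.points[:, 1],
            }
        )
        for p in patterns
    ]
    pd.concat(frames, ignore_index=True).to_csv(points_path, index=False)
    if window_path is not None:
        windows = {p.window.to_dict().__repr__() for p in patterns}
        if len(windows) != 1:
            raise ValidationError("patterns written together must share a window")
        write_window(patterns[0].window, window_path)


def read_point_patterns(points_path, window_path) -> list:
    """Read patterns grouped by (eye_id, genotype) from a coordinate CSV."""
    df = pd.read_csv(points_path)
    missing = {"eye_id", "genotype", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValidationError(f"point CSV missing columns: {sorted(missing)}")
    window = read_window(window_path)
    out = []
    for (eye, geno), sub in df.groupby(["eye_id", "genotype"], sort=True):
        out.append(
            PointPattern(sub[["x_um", "y_um"]].to_numpy(float), window, str(eye), str(geno))
        )
    return out


def write_orientation(data: OrientationDataset, path) -> None:
    data.records.to_csv(path, index=False)


def read_orientation(path) -> OrientationDataset:
    df = pd.read_csv(path)
    missing = set(ORIENTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"orientation CSV missing columns: {sorted(missing)}")
    return OrientationDataset(df)


def write_assays(assays, path) -> None:
    rows = [
        {
            "assay_id": a.assay_id,
            "genotype": a.genotype,
            "sex": a.sex,
            "n_total": a.n_total,
            "tube0": a.tube_counts[0],
            "tube1": a.tube_counts[1],
            "tube2": a.tube_counts[2],
            "tube3": a.tube_counts[3],
        }
        for a in assays
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assays(path) -> list:
    df = pd.read_csv(path)
    required = {"assay_id", "genotype", "sex", "n_total", "tube0", "tube1", "tube2", "tube3"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"assay CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        counts = (int(row.tube0), int(row.tube1), int(row.tube2), int(row.tube3))
        if sum(counts) != int(row.n_total):
            raise ValidationError(
                f"assay {row.assay_id!r}: tube counts sum to {sum(counts)}, "
                f"n_total says {int(row.n_total)}"
            )
        out.append(PhototaxisAssay(str(row.assay_id), str(row.genotype), str(row.sex), counts))
    return out


def write_rdf_curve(curve: RDFCurve, path) -> None:
    lines = [
        f"# bin_width={curve.bin_width}",
        f"# r_max={curve.r_max}",
        f"# n_points={curve.n_points}",
        f"# density={curve.density}",
        "r_center_um,g_value",
    ]
    for r, g in zip(curve.r_centers, curve.g_values):
        lines.append(f"{r},{g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rdf_curve(path) -> RDFCurve:
    meta = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key] = float(val)
        elif line and not line.startswith("r_center_um"):
            r, _, g = line.partition(",")
            rows.append((float(r), float(g)))
    arr = np.array(rows)
    return RDFCurve(
        arr[:, 0],
        arr[:, 1],
        meta["bin_width"],
        meta["r_max"],
        int(meta["n_points"]),
        meta["density"],
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_shapes(path) -> list:
    """Read shape records: list of {id, eye_id, genotype, class, vertices_um}."""
    shapes = json.loads(Path(path).read_text())
    for s in shapes:
        missing = {"id", "vertices_um"} - set(s)
        if missing:
            raise ValidationError(f"shape record missing fields: {sorted(missing)}")
    return shapes


def write_shapes(shapes, path) -> None:
    Path(path).write_text(json.dumps(shapes, indent=2) + "\n")
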