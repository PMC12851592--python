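"""End-to-end orchestration of the three analyses plus report generation.

Each ``run_*`` function consumes an :class:`AnalysisConfig`, executes one
analysis (nipple spatial order, ommatidial orientation, phototaxis) and
writes a JSON report (plus CSV tables where natural) into the output
directory. Reports embed a provenance block — the full config and seed — so
identical inputs reproduce byte-identical outputs. No multiple-comparison
adjustment is applied across groups; downstream post hoc testing is left to
standard statistics software and the reports note this.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as oio
from .circular import (
    circ_mean_resultant,
    compare_resultant_lengths,
    mirror_ventral_angles,
    stratified_permutation_test,
)
from .datatypes import OrientationDataset
from .hardcore import fit_hardcore, initialize_params
from .phototaxis import summarize_by_group
from .rdf import compare_rdf_wilcoxon, estimate_rdf, mean_rdf, rdf_r_squared, simulate_null_rdfs

log = logging.getLogger("ommaquant")

__all__ = [
    "AnalysisConfig",
    "run_nipple_analysis",
    "run_orientation_analysis",
    "run_phototaxis_analysis",
    "run_all",
]

_NOTE = (
    "No multiple-comparison correction applied across groups; "
    "post hoc testing is delegated to standard statistics software."
)


@dataclass
class AnalysisConfig:
    """Inputs and settings for one pipeline run. Lengths in μm."""

    # input tables
    points_csv: str | None = None
    window_json: str | None = None
    angles_csv: str | None = None
    assays_csv: str | None = None
    # RDF settings
    bin_width: float = 0.1
    r_max: float = 5.0
    d_min: float = 0.5
    n_null_sims: int = 50
    # permutation settings
    n_permutations: int = 10_000
    mirror_ventral: bool = True
    pure_genotype_only: bool = True
    # general
    seed: int = 0
    output_dir: str = "ommaquant_out"
    phototaxis_group_keys: tuple = ("genotype",)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phototaxis_group_keys"] = list(self.phototaxis_group_keys)
        return d


def _provenance(config: AnalysisConfig) -> dict:
    return {"config": config.to_dict(), "seed": config.seed, "note": _NOTE}


def _require(path, what):
    if path is None or not Path(path).exists():
        raise FileNotFoundError(f"{what} not found: {path}")
    return Path(path)


def _stage(name, path, n_rows, t0):
    digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12] if path else "-"
    log.info(
        "stage=%s input_sha256=%s rows=%d wall_s=%.3f", name, digest, n_rows, time.perf_counter() - t0
    )


def run_nipple_analysis(config: AnalysisConfig) -> dict:
    """Nipple spatial-order analysis for two or more genotype groups.

    Per genotype: bin-wise mean RDF over eyes, a density-matched hard-core
    null ensemble, a paired Wilcoxon comparison against the null mean, a
    hard-core disk model fit, and the R²-vs-0.9 deviation call against the
    null mean curve.
    """
    t0 = time.perf_counter()
    pts_path = _require(config.points_csv, "point-pattern CSV")
    win_path = _require(config.window_json, "window JSON")
    patterns = oio.read_point_patterns(pts_path, win_path)
    genotypes = sorted({p.genotype for p in patterns})
    if len(genotypes) < 2:
        raise ValueError(f"need >= 2 genotype groups, found {genotypes}")
    rng = np.random.default_rng(config.seed)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {"provenance": _provenance(config), "groups": {}}
    for geno in genotypes:
        group = [p for p in patterns if p.genotype == geno]
        curves = [estimate_rdf(p, config.bin_width, config.r_max) for p in group]
        emp = mean_rdf(curves)
        # one null ensemble matched to the group's most typical pattern
        ref_pattern = group[0]
        null = simulate_null_rdfs(
            ref_pattern,
            config.d_min,
            config.n_null_sims,
            config.bin_width,
            config.r_max,
            int(rng.integers(2**31)),
        )
        wil = compare_rdf_wilcoxon(emp, null.mean)
        score = rdf_r_squared(emp, null.mean)
        try:
            fit = fit_hardcore(emp)
            fit_dict = fit.to_dict()
        except Exception as exc:  # flat curve: no model structure to fit
            fit_dict = {"error": str(exc), "converged": False}
        oio.write_rdf_curve(emp, out_dir / f"rdf_{geno}.csv")
        oio.write_rdf_curve(null.mean, out_dir / f"rdf_null_mean_{geno}.csv")
        report["groups"][geno] = {
            "n_eyes": len(group),
            "n_points_total": int(sum(p.n for p in group)),
            "wilcoxon_vs_null": {
                "statistic": wil.statistic,
                "p_value": wil.p_value,
                "n_bins_paired": wil.n_bins_paired,
            },
            "r_squared_vs_null": score.r_squared,
            "deviates_from_null": score.deviates,
            "hardcore_fit": fit_dict,
        }
    oio.write_json(report, out_dir / "nipple_report.json")
    _stage("nipple", pts_path, sum(p.n for p in patterns), t0)
    return report


def run_orientation_analysis(config: AnalysisConfig) -> dict:
    """Ommatidial-orientation analysis: per-group (μ, R) and stratified tests."""
    t0 = time.perf_counter()
    ang_path = _require(config.angles_csv, "orientation CSV")
    data = oio.read_orientation(ang_path)
    df = data.records
    if config.mirror_ventral:
        df = mirror_ventral_angles(df)
    if config.pure_genotype_only and "pure_genotype" in df.columns:
        df = df[df["pure_genotype"].astype(bool)]
    data = OrientationDataset(df)
    if df["eye_id"].nunique() == 1:
        log.warning("single eye present; stratified test has one stratum")
    per_group = {}
    for geno in data.genotypes:
        s = circ_mean_resultant(data.angles(geno))
        per_group[geno] = {"mu_deg": s.mu_deg, "R": s.R, "n": s.n}
    u2 = stratified_permutation_test(
        data, "watson_u2", config.n_permutations, config.seed
    )
    rd = compare_resultant_lengths(data, config.n_permutations, config.seed)
    report = {
        "provenance": _provenance(config),
        "per_group": per_group,
        "watson_u2": {"observed_stat": u2.observed_stat, "p_value": u2.p_value},
        "resultant_diff": {"observed_stat": rd.observed_stat, "p_value": rd.p_value},
        "n_permutations": config.n_permutations,
    }
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    oio.write_json(report, out_dir / "orientation_report.json")
    _stage("orientation", ang_path, len(data), t0)
    return report


def run_phototaxis_analysis(config: AnalysisConfig) -> dict:
    """Phototaxis scoring: per-group mean/SD/n of final-tube fractions."""
    t0 = time.perf_counter()
    assay_path = _require(config.assays_csv, "assay CSV")
    assays = oio.read_assays(assay_path)
    summary = summarize_by_group(assays, config.phototaxis_group_keys)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out_dir / "phototaxis_summary.csv", index=False)
    report = {
        "provenance": _provenance(config),
        "groups": summary.where(summary.notna(), None).to_dict(orient="records"),
    }
    oio.write_json(report, out_dir / "phototaxis_report.json")
    _stage("phototaxis", assay_path, len(assays), t0)
    return report


def run_all(config: AnalysisConfig) -> dict:
    """Run every analysis whose inputs are configured."""
    out = {}
    if config.points_csv:
        out["nipple"] = run_nipple_analysis(config)
    if config.angles_csv:
        out["orientation"] = run_orientation_analysis(config)
    if config.assays_csv:
        out["phototaxis"] = run_phototaxis_analysis(config)
    if not out:
        raise ValueError("config names no input tables; nothing to run")
    return out
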