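"""Report assembly: per-case QAM runs, cohort analyses, cohort simulation.

Two-stage workflow mirroring retrospective margin studies: a geometry stage
(`run_case`) turns one co-registered mask triplet into margin summaries and
display artifacts, and a cohort stage (`run_cohort`) turns a per-tumor
feature table into the ROC threshold sweep and the GEE recurrence models.
Every run writes a manifest with input checksums so outputs are auditable;
all numeric outputs are bit-reproducible for identical inputs and seeds.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import CohortTable, SimParams, pct_column, simulate_cohort
from .grid import load_labelmask
from .margins import compute_margin_distribution, export_margin_surface, summarize_margins
from .stats import build_models, compare_nested, threshold_sweep

__all__ = ["CaseConfig", "run_case", "run_cohort", "run_simulate", "load_scenario"]


@dataclass
class CaseConfig:
    tumor_path: Path
    ablation_path: Path
    liver_path: Path | None = None
    band_mm: float = 0.0
    thresholds_mm: tuple[float, ...] = tuple(range(11))
    output_dir: Path = Path("qam_case_out")

    def __post_init__(self) -> None:
        if self.band_mm < 0:
            raise ValueError("band_mm must be >= 0")
        th = tuple(float(t) for t in self.thresholds_mm)
        if list(th) != sorted(th):
            raise ValueError("thresholds_mm must be sorted ascending")
        self.thresholds_mm = th
        self.tumor_path = Path(self.tumor_path)
        self.ablation_path = Path(self.ablation_path)
        self.liver_path = Path(self.liver_path) if self.liver_path is not None else None
        self.output_dir = Path(self.output_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(
    out_dir: Path, inputs: list[Path], config: dict, seed: int | None, warnings_list: list[str]
) -> Path:
    manifest = {
        "tool": "qam3d",
        "version": __version__,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "seed": seed,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "warnings": warnings_list,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def run_case(config: CaseConfig) -> dict:
    """One tumor: compute the 3D-QAM and write summary, histogram, mesh, manifest.

    Returns the summary dict (also written to ``summary.json``).  Outputs
    other than the manifest timestamp are deterministic in the inputs.
    """
    for p in [config.tumor_path, config.ablation_path] + (
        [config.liver_path] if config.liver_path else []
    ):
        if not Path(p).exists():
            raise FileNotFoundError(f"input volume not found: {p}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tumor = load_labelmask(config.tumor_path, label_name="tumor")
    ablation = load_labelmask(config.ablation_path, label_name="ablation")
    liver = (
        load_labelmask(config.liver_path, label_name="liver") if config.liver_path else None
    )
    dist = compute_margin_distribution(tumor, ablation, liver=liver, band_mm=config.band_mm)
    summary = summarize_margins(dist, thresholds_mm=config.thresholds_mm)
    warn: list[str] = []
    if dist.n_excluded_subcapsular:
        warn.append(
            f"excluded {dist.n_excluded_subcapsular} of {dist.n_total_surface} "
            "surface elements as subcapsular"
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
    with open(out / "histogram.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_left_mm", "bin_right_mm", "count", "percent", "category"])
        for b in summary.histogram:
            w.writerow(
                [b["bin_left_mm"], b["bin_right_mm"], b["count"], f"{b['percent']:.6f}", b["category"]]
            )
    export_margin_surface(tumor, dist, out / "margin_surface.ply")
    inputs = [config.tumor_path, config.ablation_path] + (
        [config.liver_path] if config.liver_path else []
    )
    cfg = {
        "tumor_path": str(config.tumor_path),
        "ablation_path": str(config.ablation_path),
        "liver_path": str(config.liver_path) if config.liver_path else None,
        "band_mm": config.band_mm,
        "thresholds_mm": list(config.thresholds_mm),
    }
    _write_manifest(out, [Path(p) for p in inputs], cfg, seed=None, warnings_list=warn)
    return summary.to_dict()


def run_cohort(
    table_path: str | Path,
    output_dir: str | Path,
    x_values_mm=tuple(range(11)),
    qam_cutoff_pct_lt_1: float | None = None,
    qam_cutoff_pct_lt_5: float | None = None,
) -> dict:
    """Cohort stage: ROC sweep, Youden cutoffs, models A–D, nested comparisons."""
    table_path = Path(table_path)
    if not table_path.exists():
        raise FileNotFoundError(f"cohort table not found: {table_path}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = CohortTable.from_csv(table_path)
    sweep = threshold_sweep(cohort, x_values_mm=x_values_mm)
    cut1 = qam_cutoff_pct_lt_1
    cut5 = qam_cutoff_pct_lt_5
    for x, _roc, cut in sweep.per_threshold:
        if x == 1.0 and cut1 is None:
            cut1 = cut.cutoff
        if x == 5.0 and cut5 is None:
            cut5 = cut.cutoff
    warn_msgs: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fits = build_models(cohort, qam_cutoff_pct_lt_1=cut1, qam_cutoff_pct_lt_5=cut5)
        warn_msgs = [str(w.message) for w in caught]
    with open(out / "roc_sweep.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_mm", "auc", "youden_cutoff", "sensitivity", "specificity"])
        for x, roc, cut in sweep.per_threshold:
            w.writerow(
                [f"{x:g}", repr(roc.auc), repr(cut.cutoff), repr(cut.sensitivity), repr(cut.specificity)]
            )
        mc = sweep.mam_cutoff
        w.writerow(["mam", repr(sweep.mam_roc.auc), repr(-mc.cutoff), repr(mc.sensitivity), repr(mc.specificity)])
    with open(out / "models.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["model", "term", "or", "ci_low", "ci_high", "p", "separation_flag", "or_display"]
        )
        for fit in fits:
            for t in fit.terms:
                disp = f"{t.odds_ratio:.2f} ({t.ci95_low:.2f}, {t.ci95_high:.2f})"
                w.writerow(
                    [
                        fit.model_label,
                        t.name,
                        repr(t.odds_ratio),
                        repr(t.ci95_low),
                        repr(t.ci95_high),
                        repr(t.p_value),
                        int(fit.separation_flag),
                        disp,
                    ]
                )
    fit_by_label = {f.model_label: f for f in fits}
    with open(out / "model_comparisons.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["reduced", "full", "statistic", "p", "method"])
        for label in ("B", "C", "D"):
            full = fit_by_label[label]
            if full.cov is None:
                w.writerow(["A", label, "", "", "not comparable (failed fit)"])
                continue
            res = compare_nested(fit_by_label["A"], full)
            w.writerow(["A", label, repr(res.statistic), repr(res.p_value), res.method])
    for fit in fits:
        if fit.separation_flag:
            warn_msgs.append(
                f"model {fit.model_label}: separation detected "
                f"({'; '.join(fit.separation_detail)})"
            )
    cfg = {
        "table_path": str(table_path),
        "x_values_mm": [float(x) for x in x_values_mm],
        "qam_cutoff_pct_lt_1": cut1,
        "qam_cutoff_pct_lt_5": cut5,
    }
    _write_manifest(out, [table_path], cfg, seed=None, warnings_list=warn_msgs)
    return {
        "best_x": sweep.best_x,
        "cutoff_pct_lt_1": cut1,
        "cutoff_pct_lt_5": cut5,
        "models": {f.model_label: f for f in fits},
        "sweep": sweep,
    }


_SIM_FIELDS = {f.name for f in fields(SimParams)}


def load_scenario(path: str | Path) -> SimParams:
    """Load a simulation scenario from YAML; unknown keys are rejected loudly."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    unknown = sorted(set(raw) - _SIM_FIELDS)
    if unknown:
        raise ValueError(f"unknown scenario keys: {unknown}")
    if "tumors_per_patient_weights" in raw:
        raw["tumors_per_patient_weights"] = tuple(raw["tumors_per_patient_weights"])
    if "true_beta" in raw:
        raw["true_beta"] = {k: float(v) for k, v in raw["true_beta"].items()}
    return SimParams(**raw)


def run_simulate(
    scenario: SimParams | str | Path | None,
    seed: int,
    output_dir: str | Path,
) -> Path:
    """Simulate a cohort, write ``cohort.csv`` plus a ground-truth JSON."""
    params = (
        scenario
        if isinstance(scenario, SimParams)
        else (load_scenario(scenario) if scenario is not None else SimParams())
    )
    params = params.with_seed(seed)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = simulate_cohort(params)
    csv_path = out / "cohort.csv"
    table.to_csv(csv_path)
    truth = {
        "true_beta": params.true_beta,
        "margin_cutoff_pct": params.margin_cutoff_pct,
        "margin_mode": params.margin_mode,
        "seed": params.seed,
        "n_patients": table.n_patients,
        "n_tumors": table.n_tumors,
    }
    if "oracle_mam_mm" in table.df.columns:
        truth["oracle_mam_mm"] = {
            r.tumor_id: float(r.oracle_mam_mm) for r in table.df.itertuples()
        }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    cfg = {k: v for k, v in asdict(params).items()}
    cfg["tumors_per_patient_weights"] = list(params.tumors_per_patient_weights)
    _write_manifest(out, [csv_path], cfg, seed=seed, warnings_list=[])
    return csv_path
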