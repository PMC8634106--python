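"""Per-tumor cohort tables and the clustered-cohort simulator.

A cohort row is one ablated tumor: patient id (clustering key), the clinical
covariates used in the recurrence models (neoadjuvant chemotherapy, previous
liver resection, perivascular location, KRAS mutation, CEA level, tumor
diameter), the 3D-QAM features (minimal ablation margin and surface coverage
percentages), and the 1-year ablation-site-recurrence (ASR) label.  Patients
can contribute several tumors, and patient-level covariates (KRAS, CEA) are
constant within a patient — which is exactly why the downstream regression
uses generalized estimating equations.

The simulator inverts that model: covariates are drawn from distributions
matching a typical colorectal-liver-metastasis ablation cohort, per-tumor
margin features come from a latent Gaussian margin model (or from actual
sphere-pair phantoms in geometric mode), and ASR is Bernoulli with a logistic
linear predictor whose true coefficients are part of the scenario — so every
downstream estimator can be checked for parameter recovery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SchemaError",
    "REQUIRED_COLUMNS",
    "MODEL_A_TERMS",
    "PCT_THRESHOLDS",
    "CohortTable",
    "SimParams",
    "simulate_cohort",
]

REQUIRED_COLUMNS = [
    "patient_id",
    "tumor_id",
    "asr_1y",
    "neoadjuvant_chemo",
    "previous_resection",
    "perivascular",
    "kras_mutation",
    "cea_ug_per_l",
    "diameter_mm",
    "mam_mm",
    "pct_lt_0",
    "pct_lt_1",
    "pct_lt_5",
]

#: clinical covariates of the baseline recurrence model (model A)
MODEL_A_TERMS = [
    "neoadjuvant_chemo",
    "previous_resection",
    "perivascular",
    "kras_mutation",
    "cea_ug_per_l",
    "diameter_mm",
]

#: coverage thresholds (mm) the simulator always materializes
PCT_THRESHOLDS = tuple(range(11))

_BINARY_COLS = ["asr_1y", "neoadjuvant_chemo", "previous_resection", "perivascular"]


class SchemaError(ValueError):
    """Cohort table violates the schema; ``.messages`` lists every violation."""

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        super().__init__("cohort schema violations:\n  - " + "\n  - ".join(self.messages))


def pct_column(x: float) -> str:
    return f"pct_lt_{x:g}"


@dataclass
class CohortTable:
    """Validated per-tumor cohort table (thin wrapper over a DataFrame)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        violations = self.check(self.df)
        if violations:
            raise SchemaError(violations)
        self.df = self.df.reset_index(drop=True)

    @staticmethod
    def check(df: pd.DataFrame) -> list[str]:
        """Collect every schema violation (empty list = valid)."""
        v: list[str] = []
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            v.append(f"missing required columns: {missing}")
            return v
        if len(df) == 0:
            v.append("table has no rows")
            return v
        if df["tumor_id"].duplicated().any():
            dups = df.loc[df["tumor_id"].duplicated(), "tumor_id"].tolist()
            v.append(f"duplicate tumor_id values: {dups}")
        for col in _BINARY_COLS:
            vals = set(pd.unique(df[col].dropna()))
            if not vals <= {0, 1}:
                v.append(f"column {col} must be binary 0/1, found {sorted(vals)}")
        kras = pd.unique(df["kras_mutation"].dropna())
        if not set(kras) <= {0, 1}:
            v.append(f"kras_mutation must be 0/1/blank, found {sorted(kras)}")
        if (df["cea_ug_per_l"].dropna() < 0).any():
            v.append("cea_ug_per_l has negative values")
        if (df["diameter_mm"] <= 0).any():
            v.append("diameter_mm has nonpositive values")
        for col in ("kras_mutation", "cea_ug_per_l"):
            per_pat = df.groupby("patient_id")[col].nunique(dropna=False)
            bad = per_pat[per_pat > 1].index.tolist()
            if bad:
                v.append(f"patient-level covariate {col} varies within patient_id {bad}")
        pct_cols = [c for c in df.columns if c.startswith("pct_lt_")]
        for col in pct_cols:
            s = df[col]
            if ((s < 0) | (s > 100)).any():
                v.append(f"{col} outside [0, 100]")
        return v

    @property
    def pct_thresholds(self) -> list[float]:
        """Thresholds x for which a ``pct_lt_x`` column exists, ascending."""
        xs = []
        for c in self.df.columns:
            if c.startswith("pct_lt_"):
                xs.append(float(c[len("pct_lt_"):]))
        return sorted(xs)

    @property
    def n_patients(self) -> int:
        return int(self.df["patient_id"].nunique())

    @property
    def n_tumors(self) -> int:
        return int(len(self.df))

    def to_csv(self, path: str | Path | None = None) -> str | Path:
        """Write the canonical CSV (required columns first, blanks for missing)."""
        extra = [c for c in self.df.columns if c not in REQUIRED_COLUMNS]
        out = self.df[REQUIRED_COLUMNS + extra]
        if path is None:
            buf = io.StringIO()
            out.to_csv(buf, index=False, float_format="%.6g")
            return buf.getvalue()
        out.to_csv(path, index=False, float_format="%.6g")
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, dtype={"patient_id": str, "tumor_id": str})
        return cls(df)


@dataclass
class SimParams:
    """Scenario for the clustered-cohort simulator.

    Covariate distributions default to a realistic colorectal-liver-metastasis
    ablation cohort: ~2 treated tumors per patient (1–5), neoadjuvant
    chemotherapy in 34%, previous resection in 13%, perivascular location in
    25% of tumors, KRAS mutated in half of the assessable patients with 8.5%
    of patients missing the assay, log-normal CEA (median 3.6 ug/L, IQR
    1.9–7.8) and log-normal tumor diameter (median 13 mm, IQR 10–20).

    The latent margin model draws a per-tumor margin-distribution mean
    ``mu ~ N(margin_mu_mean, margin_mu_sd)`` and spread ``s``; coverage
    percentages are ``pct_lt_x = 100 * Phi((x - mu)/s)`` and the minimal
    margin is ``mu - 2 s``.  ASR is Bernoulli with logistic linear predictor
    ``true_beta . (1, covariates, I(pct_lt_1 > margin_cutoff_pct))``.
    """

    n_patients: int = 400
    tumors_per_patient_weights: tuple[float, ...] = (0.45, 0.30, 0.15, 0.07, 0.03)
    chemo_prob: float = 0.34
    resection_prob: float = 0.128
    perivascular_prob: float = 0.246
    kras_mut_prob: float = 0.5
    kras_missing_frac: float = 0.085
    cea_log_mu: float = 1.281
    cea_log_sigma: float = 1.046
    diameter_log_mu: float = 2.565
    diameter_log_sigma: float = 0.514
    diameter_range_mm: tuple[float, float] = (5.0, 45.0)
    margin_mu_mean: float = 4.0
    margin_mu_sd: float = 2.0
    margin_sigma_mean: float = 1.5
    margin_sigma_sd: float = 0.5
    margin_sigma_floor: float = 0.5
    margin_cutoff_pct: float = 23.0
    true_beta: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": -2.5,
            "neoadjuvant_chemo": 0.3,
            "previous_resection": -0.4,
            "perivascular": 0.3,
            "kras_mutation": -0.5,
            "cea_ug_per_l": 0.01,
            "diameter_mm": 0.03,
            "qam_lt1_gt_cutoff": float(np.log(4.0)),
        }
    )
    margin_mode: str = "abstract"  # "abstract" | "geometric"
    geometric_spacing_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.tumors_per_patient_weights, dtype=float)
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(w) != 5 or np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("tumors_per_patient_weights must be 5 nonnegative weights summing to 1")
        if w.sum() == 0:
            raise ValueError("degenerate tumors-per-patient weights")
        if self.margin_mode not in ("abstract", "geometric"):
            raise ValueError(f"unknown margin_mode {self.margin_mode!r}")

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=int(seed))


def _geometric_margin_features(
    rng: np.random.Generator, diameter_mm: float, target_mam_mm: float, spacing_mm: float
) -> tuple[dict[str, float], float]:
    """Build a sphere-pair phantom realizing ``target_mam_mm`` and measure it."""
    from .margins import compute_margin_distribution, summarize_margins
    from .phantom import make_phantom_case, sphere_pair_grid

    r = max(3.0, diameter_mm / 2.0)
    target = float(np.clip(target_mam_mm, -3.0, 4.5))
    R = r + 5.0
    d = 5.0 - target  # oracle MAM = R - (r + d) = target
    spec = sphere_pair_grid(r, R, d, spacing_mm=spacing_mm)
    case = make_phantom_case(spec)
    dist = compute_margin_distribution(case.tumor, case.ablation)
    summary = summarize_margins(dist, thresholds_mm=PCT_THRESHOLDS)
    feats = {"mam_mm": summary.mam_mm}
    for x in PCT_THRESHOLDS:
        feats[pct_column(x)] = summary.pct_below[float(x)]
    return feats, case.oracle.min_margin_mm


def simulate_cohort(params: SimParams) -> CohortTable:
    """Draw a clustered cohort; deterministic given ``params.seed``.

    Each patient uses an independent substream derived from the master seed,
    so regenerating a subset of patients reproduces their rows exactly.
    KRAS missingness masks the observed value only — the true value still
    drives the outcome, i.e. missingness is completely at random.
    In geometric mode the margin features are measured on per-tumor sphere
    phantoms and the analytic minimal margin is kept in ``oracle_mam_mm``.
    """
    beta = params.true_beta
    rows: list[dict] = []
    for pid in range(params.n_patients):
        rng = np.random.default_rng([int(params.seed) % (2**31), pid])
        n_tumors = int(rng.choice(np.arange(1, 6), p=params.tumors_per_patient_weights))
        chemo = int(rng.random() < params.chemo_prob)
        resection = int(rng.random() < params.resection_prob)
        kras_true = int(rng.random() < params.kras_mut_prob)
        kras_missing = rng.random() < params.kras_missing_frac
        cea = float(rng.lognormal(params.cea_log_mu, params.cea_log_sigma))
        for t in range(n_tumors):
            peri = int(rng.random() < params.perivascular_prob)
            diameter = float(
                np.clip(
                    rng.lognormal(params.diameter_log_mu, params.diameter_log_sigma),
                    *params.diameter_range_mm,
                )
            )
            mu = float(rng.normal(params.margin_mu_mean, params.margin_mu_sd))
            s = float(
                max(params.margin_sigma_floor, rng.normal(params.margin_sigma_mean, params.margin_sigma_sd))
            )
            oracle_mam = np.nan
            if params.margin_mode == "geometric":
                feats, oracle_mam = _geometric_margin_features(
                    rng, diameter, mu - 2.0 * s, params.geometric_spacing_mm
                )
            else:
                feats = {"mam_mm": mu - 2.0 * s}
                for x in PCT_THRESHOLDS:
                    feats[pct_column(x)] = 100.0 * float(norm.cdf((x - mu) / s))
            margin_ind = float(feats[pct_column(1)] > params.margin_cutoff_pct)
            eta = (
                beta["intercept"]
                + beta["neoadjuvant_chemo"] * chemo
                + beta["previous_resection"] * resection
                + beta["perivascular"] * peri
                + beta["kras_mutation"] * kras_true
                + beta["cea_ug_per_l"] * cea
                + beta["diameter_mm"] * diameter
                + beta["qam_lt1_gt_cutoff"] * margin_ind
            )
            asr = int(rng.random() < expit(eta))
            row = {
                "patient_id": f"P{pid:05d}",
                "tumor_id": f"P{pid:05d}_T{t + 1}",
                "asr_1y": asr,
                "neoadjuvant_chemo": chemo,
                "previous_resection": resection,
                "perivascular": peri,
                "kras_mutation": np.nan if kras_missing else kras_true,
                "cea_ug_per_l": cea,
                "diameter_mm": diameter,
            }
            row.update(feats)
            if params.margin_mode == "geometric":
                row["oracle_mam_mm"] = oracle_mam
            rows.append(row)
    df = pd.DataFrame(rows)
    df["kras_mutation"] = df["kras_mutation"].astype(float)  # nullable
    return CohortTable(df)
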