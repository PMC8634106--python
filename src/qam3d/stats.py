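"""Cohort statistics for ablation-site-recurrence (ASR) prediction.

Implements the analysis chain applied to per-tumor 3D-QAM features:

* ROC curves over the coverage percentages ``pct_lt_x`` for x = 0..10 mm
  (plus the minimal ablation margin, sign-flipped so that larger score =
  higher risk everywhere), AUC by the rank (Mann–Whitney) statistic, and
  Youden-index cutoff selection;
* Mann–Whitney U group comparisons (exact enumeration for small samples,
  tie-corrected normal approximation otherwise);
* logistic regression via generalized estimating equations with an
  independence working correlation and a robust (sandwich) covariance
  clustered on patient — the appropriate marginal model when several tumors
  of one patient share patient-level covariates;
* the four recurrence models: A = clinical covariates only, B = A + MAM
  (continuous), C = A + I(pct_lt_1 > cutoff), D = A + I(pct_lt_5 > cutoff),
  with explicit detection of (quasi-)complete separation, which is reported
  as a flag on the fit rather than an exception — a zero-event stratum is a
  finding, not a crash;
* nested-model comparison as a robust Wald chi-square test on the added
  terms (GEE has no likelihood, so no likelihood-ratio ANOVA exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .cohort import MODEL_A_TERMS, CohortTable, pct_column

__all__ = [
    "RocResult",
    "CutoffResult",
    "TestResult",
    "TermEstimate",
    "GeeFit",
    "SeparationReport",
    "SweepResult",
    "roc_curve",
    "youden_cutoff",
    "threshold_sweep",
    "mann_whitney",
    "fit_gee_logistic",
    "detect_separation",
    "build_models",
    "compare_nested",
]

Z975 = 1.959964  # normal 97.5th percentile used for all 95% CIs


@dataclass
class RocResult:
    score_name: str
    points: list[tuple[float, float, float]]  # (threshold, sensitivity, specificity)
    auc: float


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str


@dataclass
class TermEstimate:
    name: str
    beta: float
    robust_se: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float


@dataclass
class GeeFit:
    model_label: str
    terms: list[TermEstimate]
    n_tumors: int
    n_patients: int
    converged: bool
    separation_flag: bool
    separation_detail: list[str] = field(default_factory=list)
    cov: np.ndarray | None = None  # robust covariance, term order as in `terms`

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class SeparationReport:
    flag: bool
    messages: list[str] = field(default_factory=list)


@dataclass
class SweepResult:
    per_threshold: list[tuple[float, RocResult, CutoffResult]]
    mam_roc: RocResult
    mam_cutoff: CutoffResult
    best_x: float


def roc_curve(scores, labels, score_name: str = "score") -> RocResult:
    """Empirical ROC for a risk-increasing score (positive when score >= t).

    Thresholds are the sorted unique scores; AUC is the rank statistic
    (Mann–Whitney with ties counted 1/2), which equals the trapezoidal area
    under the empirical curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(s) != len(y):
        raise ValueError("scores and labels have different lengths")
    if not (set(np.unique(y)) <= {0, 1}) or len(np.unique(y)) < 2:
        raise ValueError("single-class outcome: labels must contain both 0 and 1")
    y = y.astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    ranks = sps.rankdata(s)
    auc = (float(ranks[y == 1].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    points = []
    for t in np.unique(s):
        pred = s >= t
        sens = float(np.count_nonzero(pred & (y == 1))) / n_pos
        spec = float(np.count_nonzero(~pred & (y == 0))) / n_neg
        points.append((float(t), sens, spec))
    return RocResult(score_name=score_name, points=points, auc=float(auc))


def youden_cutoff(roc: RocResult) -> CutoffResult:
    """Cutoff maximizing J = sensitivity + specificity - 1 (ties -> smallest)."""
    if not roc.points:
        raise ValueError("ROC has no points")
    best = None
    for t, sens, spec in roc.points:  # points ascend in threshold
        j = sens + spec - 1.0
        if best is None or j > best[3] + 1e-12:
            best = (t, sens, spec, j)
    return CutoffResult(cutoff=best[0], sensitivity=best[1], specificity=best[2], youden_j=best[3])


def threshold_sweep(
    cohort: CohortTable, x_values_mm=tuple(range(11)), outcome: str = "asr_1y"
) -> SweepResult:
    """ROC per coverage threshold x (score = pct_lt_x) plus the MAM ROC.

    ``best_x`` is the x with maximal AUC, ties broken toward smaller x.  MAM
    is protective, so its score is ``-mam_mm`` to keep the risk-increasing
    orientation.  Tumors are treated as independent here (no clustering
    adjustment), matching standard tumor-level ROC practice.
    """
    df = cohort.df
    y = df[outcome].to_numpy()
    missing = [pct_column(x) for x in x_values_mm if pct_column(x) not in df.columns]
    if missing:
        raise ValueError(f"cohort lacks coverage features: {missing}")
    per = []
    best_x, best_auc = None, -np.inf
    for x in x_values_mm:
        roc = roc_curve(df[pct_column(x)].to_numpy(), y, score_name=pct_column(x))
        cut = youden_cutoff(roc)
        per.append((float(x), roc, cut))
        if roc.auc > best_auc + 1e-12:
            best_auc, best_x = roc.auc, float(x)
    mam_roc = roc_curve(-df["mam_mm"].to_numpy(), y, score_name="neg_mam_mm")
    return SweepResult(
        per_threshold=per, mam_roc=mam_roc, mam_cutoff=youden_cutoff(mam_roc), best_x=best_x
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: pairs with a > b plus half the ties."""
    diff = a[:, None] - b[None, :]
    return float(np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0))


def mann_whitney(group_a, group_b, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann–Whitney U test.

    For combined n <= ``exact_max_n`` the null distribution of U is obtained
    by full enumeration of all group assignments of the pooled values (valid
    under ties), and the two-sided p-value is the probability of a deviation
    from the null mean at least as large as observed.  Larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    na, nb = len(a), len(b)
    if na + nb <= exact_max_n:
        pooled = np.concatenate([a, b])
        n = na + nb
        mu = na * nb / 2.0
        dev = abs(u_obs - mu)
        hits = 0
        for idx_a in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        p = hits / comb(n, na)
        return TestResult(statistic=u_obs, p_value=float(p), method="exact enumeration")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), method="normal approximation"
    )


def _design(df: pd.DataFrame, term_names: list[str], outcome: str, cluster: str):
    cols = [outcome, cluster] + list(term_names)
    data = df[cols].dropna()
    y = data[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy(dtype=float) for t in term_names])
    names = ["intercept"] + list(term_names)
    groups = data[cluster].to_numpy()
    return data, y, X, names, groups


def fit_gee_logistic(
    cohort: CohortTable | pd.DataFrame,
    term_names: list[str],
    cluster: str = "patient_id",
    outcome: str = "asr_1y",
    model_label: str = "",
    check_separation: bool = True,
) -> GeeFit:
    """Logistic GEE with independence working correlation, clustered sandwich SEs.

    Missing values among the used terms are dropped (complete-case at the
    tumor level).  With one tumor per patient this reduces exactly to
    ordinary logistic maximum likelihood.  Separation is detected up front;
    a flagged fit is still attempted and returned (never raised), mirroring
    how a zero-event stratum should be reported as a finding.
    """
    import statsmodels.api as sm

    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    data, y, X, names, groups = _design(df, term_names, outcome, cluster)
    n_clusters = len(pd.unique(groups))
    if n_clusters < 2:
        raise ValueError("GEE requires at least 2 clusters")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class outcome")
    sep = SeparationReport(False, [])
    if check_separation and term_names:
        sep = detect_separation(data, list(term_names), outcome=outcome)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(
                y,
                X,
                groups=groups,
                family=sm.families.Binomial(),
                cov_struct=sm.cov_struct.Independence(),
            )
            res = model.fit(maxiter=100, ctol=1e-10)
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        bse = np.sqrt(np.diag(cov))
        pvals = np.asarray(res.pvalues, dtype=float)
        converged = bool(getattr(res, "converged", True))
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
            converged = False
    except Exception as exc:  # numerical failure: report, never raise
        params = np.full(len(names), np.nan)
        cov = None
        bse = np.full(len(names), np.nan)
        pvals = np.full(len(names), np.nan)
        converged = False
        sep = SeparationReport(True, sep.messages + [f"fit failed: {exc}"])
    terms = [
        TermEstimate(
            name=nm,
            beta=float(b),
            robust_se=float(se),
            odds_ratio=float(np.exp(b)),
            ci95_low=float(np.exp(b - Z975 * se)),
            ci95_high=float(np.exp(b + Z975 * se)),
            p_value=float(p),
        )
        for nm, b, se, p in zip(names, params, bse, pvals)
    ]
    return GeeFit(
        model_label=model_label,
        terms=terms,
        n_tumors=int(len(y)),
        n_patients=int(n_clusters),
        converged=converged,
        separation_flag=bool(sep.flag),
        separation_detail=sep.messages,
        cov=cov,
    )


def _damped_logistic_betas(X: np.ndarray, y: np.ndarray, max_iter: int = 25) -> np.ndarray:
    """Guarded Newton iterations for the separation probe (diverges if separated)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        h = (X * w[:, None]).T @ X + 1e-8 * np.eye(X.shape[1])
        step = np.linalg.solve(h, X.T @ (y - p))
        nrm = np.linalg.norm(step)
        if nrm > 5.0:  # cap step length; a separated direction still accumulates
            step *= 5.0 / nrm
        beta = beta + step
    return beta


def detect_separation(
    cohort: CohortTable | pd.DataFrame,
    term_names: list[str],
    outcome: str = "asr_1y",
    beta_threshold: float = 10.0,
    max_iter: int = 25,
) -> SeparationReport:
    """Detect (quasi-)complete separation among the model terms.

    Binary terms are flagged when any cell of the term-by-outcome 2x2 table
    is empty (e.g. no event in one stratum).  Continuous terms are probed by
    damped Newton logistic iterations on standardized covariates: a
    coefficient whose magnitude exceeds ``beta_threshold`` within
    ``max_iter`` iterations is diverging, the signature of quasi-complete
    separation.
    """
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    data = df[[outcome] + list(term_names)].dropna()
    y = data[outcome].to_numpy(dtype=float)
    messages: list[str] = []
    continuous: list[str] = []
    for t in term_names:
        x = data[t].to_numpy(dtype=float)
        if set(np.unique(x)) <= {0.0, 1.0}:
            for stratum in (0.0, 1.0):
                sel = x == stratum
                if not sel.any():
                    continue
                events = int(y[sel].sum())
                if events == 0:
                    messages.append(f"zero events in stratum {t}={int(stratum)}")
                elif events == int(sel.sum()):
                    messages.append(f"zero non-events in stratum {t}={int(stratum)}")
        else:
            continuous.append(t)
    if continuous and len(np.unique(y)) == 2:
        cols = []
        for t in term_names:
            x = data[t].to_numpy(dtype=float)
            sd = x.std()
            cols.append((x - x.mean()) / sd if sd > 0 else x * 0.0)
        X = np.column_stack([np.ones(len(y))] + cols)
        betas = _damped_logistic_betas(X, y, max_iter=max_iter)
        for name, b in zip(term_names, betas[1:]):
            if name in continuous and abs(b) > beta_threshold:
                messages.append(
                    f"diverging coefficient for continuous term {name} "
                    f"(|beta_std| = {abs(b):.1f} after {max_iter} damped iterations)"
                )
    return SeparationReport(flag=bool(messages), messages=messages)


def build_models(
    cohort: CohortTable,
    qam_cutoff_pct_lt_1: float | None = None,
    qam_cutoff_pct_lt_5: float | None = None,
    cluster: str = "patient_id",
) -> list[GeeFit]:
    """Fit the four recurrence models A–D on one cohort.

    A: clinical covariates only; B: A + MAM (continuous, mm); C: A +
    I(pct_lt_1 > cutoff); D: A + I(pct_lt_5 > cutoff).  Cutoffs default to
    the Youden-optimal thresholds of the corresponding ROC curves.  Tumors
    with missing KRAS are dropped (complete-case); each model is fit
    independently so one failure never aborts the others.
    """
    df = cohort.df.copy()
    n_missing = int(df["kras_mutation"].isna().sum())
    if n_missing:
        warnings.warn(
            f"dropping {n_missing} tumors with missing KRAS status (complete-case)",
            stacklevel=2,
        )
    if qam_cutoff_pct_lt_1 is None:
        qam_cutoff_pct_lt_1 = youden_cutoff(
            roc_curve(df["pct_lt_1"].to_numpy(), df["asr_1y"].to_numpy())
        ).cutoff
    if qam_cutoff_pct_lt_5 is None:
        qam_cutoff_pct_lt_5 = youden_cutoff(
            roc_curve(df["pct_lt_5"].to_numpy(), df["asr_1y"].to_numpy())
        ).cutoff
    df["qam_lt1_gt_cutoff"] = (df["pct_lt_1"] > qam_cutoff_pct_lt_1).astype(float)
    df["qam_lt5_gt_cutoff"] = (df["pct_lt_5"] > qam_cutoff_pct_lt_5).astype(float)
    model_terms = {
        "A": MODEL_A_TERMS,
        "B": MODEL_A_TERMS + ["mam_mm"],
        "C": MODEL_A_TERMS + ["qam_lt1_gt_cutoff"],
        "D": MODEL_A_TERMS + ["qam_lt5_gt_cutoff"],
    }
    fits = []
    for label, terms in model_terms.items():
        fits.append(
            fit_gee_logistic(df, terms, cluster=cluster, model_label=label)
        )
    return fits


def compare_nested(fit_reduced: GeeFit, fit_full: GeeFit) -> TestResult:
    """Robust Wald chi-square on the terms added by the full model.

    GEE has no likelihood, so nested models are compared by a working Wald
    test: ``b' V^{-1} b`` over the added coefficients with the full model's
    robust covariance, chi-square with df = number of added terms.
    """
    red = set(fit_reduced.term_names)
    full = fit_full.term_names
    if not red <= set(full):
        raise ValueError("models are not nested (reduced terms not a subset of full)")
    if fit_reduced.n_tumors != fit_full.n_tumors:
        raise ValueError("models were fit on different rows")
    added = [t for t in full if t not in red]
    if not added:
        return TestResult(statistic=0.0, p_value=1.0, method="wald chi-square (df=0)")
    if fit_full.cov is None:
        raise ValueError("full model has no covariance (failed fit)")
    idx = [full.index(t) for t in added]
    b = np.array([fit_full.terms[i].beta for i in idx])
    v = fit_full.cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(v, b))
    p = float(sps.chi2.sf(stat, df=len(added)))
    return TestResult(statistic=stat, p_value=p, method=f"wald chi-square (df={len(added)})")
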