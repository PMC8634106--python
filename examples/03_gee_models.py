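"""Fit the four recurrence models (GEE logistic, patient-clustered) on a
simulated cohort and show the margin effect plus a constructed separation.

Model A uses clinical covariates only; B adds the minimal ablation margin as
a continuous term; C adds a binary indicator of poor coverage (> cutoff % of
surface with margin < 1 mm); D adds the analogous 5-mm indicator.  A cohort
in which no recurrence occurs in the well-covered stratum makes model D
unidentifiable (complete separation) -- reported as a flag, not a crash.
"""

import warnings

from qam3d import CohortTable, SimParams, build_models, compare_nested, simulate_cohort

cohort = simulate_cohort(SimParams(n_patients=400, seed=2))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fits = build_models(cohort)

for fit in fits:
    print(f"\nModel {fit.model_label}  ({fit.n_tumors} tumors, {fit.n_patients} patients, "
          f"separation={fit.separation_flag})")
    for t in fit.terms:
        print(f"  {t.name:22s} OR {t.odds_ratio:8.2f}  ({t.ci95_low:.2f}, {t.ci95_high:.2f})  p={t.p_value:.3f}")

by = {f.model_label: f for f in fits}
cmp_c = compare_nested(by["A"], by["C"])
print(f"\nA vs C (Wald on added margin term): chi2={cmp_c.statistic:.2f}, p={cmp_c.p_value:.4f}")

# constructed separation: zero events in the low-coverage stratum
df = cohort.df.copy()
df.loc[df.pct_lt_5 <= 45.0, "asr_1y"] = 0
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fits2 = build_models(CohortTable(df), qam_cutoff_pct_lt_1=23.0, qam_cutoff_pct_lt_5=45.0)
d = [f for f in fits2 if f.model_label == "D"][0]
print(f"\nconstructed zero-cell cohort -> model D separation_flag={d.separation_flag}")
print("detail:", "; ".join(d.separation_detail))
# The margin indicator in model C should carry the largest standardized effect,
# since the simulated outcome is driven by coverage below 1 mm (true OR = 4).
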