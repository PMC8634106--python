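"""Simulate a clustered ablation cohort and run the ROC threshold sweep.

The simulator draws patients with 1-5 treated tumors, clinical covariates
matching a typical colorectal-liver-metastasis cohort, per-tumor margin
coverage features, and a 1-year ablation-site-recurrence outcome generated
from a logistic model whose true coefficients are known.  The sweep then asks
which coverage threshold (pct of surface with margin < x mm) best
discriminates recurring tumors.
"""

from qam3d import SimParams, simulate_cohort, threshold_sweep

params = SimParams(n_patients=400, seed=1)
cohort = simulate_cohort(params)
print(f"cohort: {cohort.n_patients} patients, {cohort.n_tumors} tumors, "
      f"{cohort.df.asr_1y.mean()*100:.1f}% 1-year recurrence")

sweep = threshold_sweep(cohort)
print("\n x (mm)   AUC    Youden cutoff (% surface)")
for x, roc, cut in sweep.per_threshold:
    print(f"  {x:4.0f}   {roc.auc:.3f}   > {cut.cutoff:.1f}% (J={cut.youden_j:.2f})")
print(f"  MAM    {sweep.mam_roc.auc:.3f}")
print(f"\nbest discriminating coverage threshold: {sweep.best_x:g} mm")
# The generating model drives recurrence through coverage below 1 mm, so the
# sweep should peak at (or next to) x = 1 with the remaining thresholds decaying.
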