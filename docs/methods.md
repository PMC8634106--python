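# Methods

## The margin model

A treated tumor is represented by two co-registered binary masks on one voxel
grid: the tumor (pre-ablation) and the final ablation zone (post-ablation;
re-ablations must be unioned by the caller).  The 3D quantitative ablation
margin (3D-QAM) is the distribution over the tumor surface of the signed
Euclidean distance to the ablation boundary, positive where the surface lies
inside the ablation zone.  Its minimum is the minimal ablation margin (MAM);
`pct_below(x)` is the strict percentage of assessable surface with margin
< x mm.  All geometry is computed in physical millimetres, so anisotropic
grids (e.g. 0.7×0.7×1.0 mm CT) are handled directly; masks are binarized at
0.5 by default (accommodating 0/1, 0/255 and probabilistic masks), and
near-matching grids are refused rather than silently resampled, because
silent resampling hides registration errors.

## Surface and distance estimation

Two conventions are implemented.

**Level-set convention (default).**  Each mask is converted to the symmetric
field `edt(mask) − edt(~mask)` (center-to-center Euclidean distance
transforms; outside the grid counts as background), smoothed with a Gaussian
of one voxel, and de-biased by the second-order heat-kernel term
`Σᵢ σᵢ²/2 · ∂²φ/∂xᵢ²` — smoothing otherwise shifts a curved zero level by
σ²·κ/2 (≈0.04 mm for a 10 mm sphere at 0.5 mm spacing).  The tumor surface is
the marching-cubes triangulation of the corrected field at level 0; each
vertex is weighted by one third of its adjacent triangle area, and its margin
is the distance to the nearest vertex of the ablation zero-level mesh, signed
by the ablation field.  Against sphere-pair phantoms with closed-form margins
this estimator is accurate to ≤0.27 mm in MAM and ≤1.7 percentage points in
coverage fractions at 0.5 mm spacing.  Masks too small to carry a smoothed
zero level (a few voxels) fall back automatically to the voxel convention.

**Voxel convention (`refine=False`).**  Surface elements are the occupied
voxels with an unoccupied 6-neighbor, sampled at their centers with equal
weight, and the margin is the voxel-center signed Euclidean field of the
ablation mask (occupied voxels: +distance to nearest unoccupied voxel
center; unoccupied: −distance to nearest occupied).  This convention is
simpler and fully discrete but carries a systematic half-voxel-scale bias
(coverage-fraction errors up to ~9 points at 0.5 mm spacing on the same
phantoms), which is why it is not the default.  A mask identical to itself
has margin +1 voxel under this convention and margin ≈ 0 under the level-set
convention; the latter is the physically meaningful answer for coincident
boundaries.

One intrinsic caveat: when the true margin distribution is an atom exactly at
a queried threshold (a concentric phantom probed at exactly R−r), the strict
fraction is discontinuous there and any unbiased estimator necessarily
scatters measured margins to both sides; such degenerate cells are assessed
by bracketing the atom rather than by the point value.

## Subcapsular exclusion

Subcapsular tumors abut the liver capsule, where no liver tissue exists to
ablate, so capsule-adjacent surface must not count against the margin.  With
a liver mask supplied, a surface element is excluded when it lies outside
the liver or within `band_mm` of the liver boundary (per the liver signed
distance field).  The default `band_mm = 0` excludes contact/extrahepatic
surface only; the band is exposed as a parameter because published
subcapsular corrections differ in width.  Exclusion changes membership only,
never the retained margin values, and the excluded count is reported.

## Synthetic phantoms

`rasterize_ellipsoid` occupies every voxel whose center satisfies the
ellipsoid inequality.  For a spherical tumor (radius r, center o) and
spherical ablation (radius R, center c, offset d = |o−c|), the margin at a
surface point is `R − |p−c|`, the MAM is `R − (r+d)`, and the fraction of
tumor surface with margin < x is the spherical-cap area fraction
`(1+u)/2, u = (r²+d²−(R−x)²)/(2rd)` (clipped to [−1,1]; a step at `x = R−r`
in the concentric limit).  These closed forms are the ground truth for the
geometric accuracy tests.

## Cohort simulator

The simulator generates the study conditions for the statistical layer: a
cohort of patients with 1–5 treated colorectal liver metastases each
(weights 0.45/0.30/0.15/0.07/0.03; median 2), patient-level covariates —
neoadjuvant chemotherapy 34%, previous resection 12.8%, KRAS mutated in 50%
of assessable patients with 8.5% missing assays, log-normal CEA (median
3.6 µg/L, IQR ≈ 1.9–7.8) — and tumor-level covariates: perivascular location
24.6% and log-normal diameter (median 13 mm, IQR ≈ 10–20, clipped to
5–45 mm).  Margin features come from a latent Gaussian model: each tumor
draws a margin-distribution mean `µ ~ N(4, 2²)` mm and spread
`s = max(0.5, N(1.5, 0.5²))`; then `pct_below(x) = 100·Φ((x−µ)/s)` and
`MAM = µ − 2s`.  This yields MAMs centred near 0 mm and a ~20% prevalence of
the poor-coverage indicator `I(pct_below(1) > 23%)`.  In geometric mode the
features are instead measured on per-tumor sphere-pair phantoms built to a
target MAM, with the analytic MAM retained for end-to-end checks.

The outcome is Bernoulli with logistic linear predictor over (intercept,
chemotherapy, resection, perivascular, KRAS, CEA, diameter, poor-coverage
indicator).  Default coefficients are chosen for test power, not as
population estimates: a dominant margin effect ln 4 on the indicator, modest
clinical effects (|β| ≤ 0.5; 0.01 per µg/L CEA, 0.03 per mm diameter), and
intercept −2.5, calibrated so the marginal 1-year ASR rate is ≈15%, the rate
typical of ablation cohorts in this setting.  KRAS missingness masks the
observed value only (missing completely at random); the true value still
drives the outcome.  Randomness uses per-patient substreams derived from the
master seed, so any subset of patients regenerates identically.

What the simulator does **not** emulate: registration error between pre- and
post-ablation scans, segmentation variability, correlated margin features
within a patient, non-ellipsoidal ablation shapes, and informative
missingness.  Passing tests therefore demonstrate correctness of the
computational chain under known generating models, not clinical performance
on real images.

## Statistical layer

ROC curves treat tumors as independent (a recorded limitation — the cohort
is clustered); thresholds are the observed scores, positives classified at
score ≥ t, AUC computed by the rank statistic with ties counted ½.
Protective scores (MAM) are negated so one risk-increasing orientation
serves all curves.  The Youden cutoff maximizes sensitivity + specificity −
1, ties broken toward the smaller cutoff.  Mann–Whitney tests are exact by
full enumeration of group assignments for combined n ≤ 12 (valid under
ties), and tie-corrected normal approximation otherwise.

The recurrence models are logistic GEE fits with an independence working
correlation and a robust sandwich covariance clustered on patient — the
marginal model appropriate when patients contribute several tumors sharing
patient-level covariates.  With one tumor per patient this reduces exactly
to ordinary logistic maximum likelihood (verified to 1e-6 against an
independent Newton–Raphson oracle).  CIs use the normal 97.5th percentile
1.959964; p-values are two-sided Wald.  Tumors with missing KRAS are dropped
(complete-case) with the count logged; raw CEA values enter untransformed.

Separation is probed before each fit: any binary term with an empty
term-by-outcome cell is flagged (with the offending stratum named), and
continuous terms are probed by 25 guarded Newton iterations on standardized
covariates, flagging coefficients whose magnitude exceeds 10 — the signature
of quasi-complete separation.  A flagged model is still attempted and
returned with `separation_flag=True`; a zero-event stratum is a scientific
finding about the cohort, not an error condition.  Nested models are
compared by a robust Wald chi-square on the added terms (GEE has no
likelihood, so no likelihood-ratio test exists); this is a documented
stand-in, not an equivalence claim for likelihood-based ANOVA.

## Numerical choices and defaults

| parameter | default | rationale |
|---|---|---|
| binarize threshold | 0.5 | deterministic across mask dialects |
| smoothing | 1 voxel (σ) | suppresses rasterization staircase; curvature term removes its bias |
| subcapsular band | 0 mm | contact-only exclusion; band exposed for wider definitions |
| coverage thresholds | 0–10 mm, 1 mm steps | spans the clinically discussed 0–10 mm margin range |
| co-registration tolerance | 1e-3 relative spacing, 0.1 mm origin | far below voxel scale; anything larger indicates a registration problem |
| histogram bins | 1 mm, integer edges, left-closed | matches threshold convention (strict `<`) |
| GEE iterations | 100, parameter tolerance 1e-10 | tight enough that independence GEE matches logistic ML to 1e-6 |
| tie-breaks | smallest threshold / lowest index | determinism |

Problem sizes in the validation suite — phantoms ≤ 112³ voxels at 0.5 mm,
cohorts of 400–2000 patients, 100 replicate fits for coverage studies — were
chosen so the full suite demonstrates convergence-level agreement with the
analytic oracles while remaining quick to run on a laptop.

## Known limitations

* Margins are geometric; no correction is modeled for residual registration
  error between pre- and post-ablation scans.
* Tumor-level ROC ignores patient clustering (the GEE layer does not).
* The voxel convention's equal element weighting over-represents oblique
  staircase surface; use the default level-set convention when coverage
  fractions matter.
* The subcapsular band width of published correction algorithms is not
  standardized; results near the capsule depend on the chosen `band_mm`.
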