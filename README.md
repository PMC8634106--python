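# qam3d — 3D quantitative ablation margins and recurrence statistics

After thermal ablation of a liver tumor, the single strongest determinant of
local treatment success is whether the ablation zone covered the whole tumor
with a sufficient safety margin.  `qam3d` quantifies that coverage in 3D: given
co-registered binary segmentations of the tumor and the ablation zone (and
optionally the liver), it computes the **3D quantitative ablation margin
(3D-QAM)** — the distribution of signed distances from every element of the
tumor surface to the ablation boundary — and the downstream statistics that
link margins to 1-year ablation-site recurrence (ASR).

It is written for interventional-radiology and surgical-oncology research
groups who need reproducible, per-tumor margin metrics and a clustered
regression layer for multi-tumor patients.

## What it computes

For a tumor surface point *p* and ablation zone *A*, the margin is the signed
Euclidean distance `m(p) = ±d(p, ∂A)` (positive inside the ablation zone).
From the distribution of `m` over the assessable tumor surface the package
reports

* **MAM** — the minimal ablation margin, `min m(p)`;
* **coverage percentages** `pct_below(x)` — the % of surface with `m < x` mm
  (strict), for x = 0…10 mm;
* the display categories *residual tumor* (`m < 0`, red), 0–5 mm (yellow),
  \>5 mm (green), plus a 1-mm histogram and a colored surface mesh (PLY).

Surface elements lying at or beyond the liver capsule (subcapsular tumors
have no liver tissue to ablate there) can be excluded via a liver mask.

The cohort layer implements the standard analysis chain: ROC curves of each
coverage threshold against ASR with Youden-index cutoffs, Mann–Whitney group
comparisons, and four logistic **GEE** models (independence working
correlation, robust covariance clustered by patient): A = clinical covariates
(neoadjuvant chemotherapy, previous resection, perivascular location, KRAS,
CEA, diameter); B = A + MAM; C = A + I(pct_below(1 mm) > cutoff);
D = A + I(pct_below(5 mm) > cutoff).  Complete separation (e.g. a zero-event
stratum) is detected and reported as a flag on the fit rather than a crash.

Because clinical CT series cannot ship with the code, a first-class synthetic
layer provides ground truth for everything: sphere-pair phantoms whose margin
distribution has a closed spherical-cap form, and a clustered cohort
simulator with a known logistic generating model.

## Worked example

```bash
python examples/01_phantom_margins.py
```

builds a phantom whose ablation sphere (R = 15 mm) is offset 7 mm from a
10 mm tumor sphere — so analytically the MAM is R − (r+d) = −2 mm and 22.86%
of the tumor surface is uncovered — and prints:

```
surface elements assessed : 7518
minimal ablation margin   : -2.01 mm (analytic -2.0)
median margin             : +2.80 mm
residual surface  (<0 mm) : 23.04 % (analytic 22.86)
surface with margin <5 mm : 67.37 % (analytic 67.50)
categories red/yellow/green: 23.0 / 44.3 / 32.6 %
```

A negative MAM with a ~23% red fraction flags a tumor whose ablation left
residual surface.  `examples/02_simulate_and_sweep.py` and
`examples/03_gee_models.py` show the cohort side: a simulated 400-patient
cohort (742 tumors, 14.3% 1-year ASR), the threshold sweep, and the four GEE
models — in which the poor-coverage indicator of model C carries an odds
ratio of 2.84 (true generating OR 4, within the CI) and dominates the
clinical covariates, while a constructed cohort with no events in the
well-covered stratum trips model D's separation flag.

## Command line

```bash
qam phantom --out ph --offset 7          # emit phantom masks (NIfTI)
qam case --tumor t.nii.gz --ablation a.nii.gz --liver l.nii.gz --out case_out
qam simulate --out sim --seed 7          # cohort CSV + ground truth
qam cohort sim/cohort.csv --out report   # sweep + models A–D
```

Every run writes a manifest with input checksums; outputs are deterministic
for identical inputs and seeds.

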