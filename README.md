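# actihr

Fused heart-rate and locomotor-activity phenotyping: a tested, reusable
pipeline that separates case from control subjects using features extracted
from paired wearable recordings — ECG-derived heart rate (HR, bpm, roughly
every 10 min) and accelerometer-derived locomotor activity (arbitrary units
in [0, 1], roughly every 5 min). The motivating application is digital
phenotyping of schizophrenia, where patients show elevated heart rate,
reduced and disorganized locomotor activity, disrupted circadian
rest–activity rhythms, and altered multiscale dynamics relative to healthy
controls, and where fusing cardiac and locomotor information improves
discrimination over either signal alone. The package targets researchers in
digital psychiatry and physiological time-series analysis who want the
complete chain — preprocessing, feature extraction, feature selection, classifier
evaluation — as reproducible, inspectable code, plus a calibrated synthetic
cohort generator so every stage is testable without access to clinical
recordings.

## What it computes

**Preprocessing.** Irregular samples are converted to exact grids: spans
longer than 1.5× the nominal collection rate (15 min for HR, 7.5 min for
activity) are flagged low-quality and never bridged; HR values below 20 bpm
are removed as artifacts; HR is resampled to 10-min and activity to 5-min
grids by zero-order hold; synchronous analyses use activity down-sampled to
10 min by averaging adjacent values. Per subject, the 10 calendar days with
the least missing data are retained; subjects with more than 10% artifacts
or missing data are rejected.

**Features** (18 per signal, 36 total):

- summary statistics: mean, median, mode, STD, IQR;
- non-parametric rest–activity metrics: L5 and M10 (sum of the least-active
  5-h / most-active 10-h circular windows of the mean 24-h profile),
  relative amplitude RA = (M10 − L5)/(M10 + L5), interdaily stability
  IS = n·Σ_h(x̄_h − x̄)² / (p·Σ_i(x_i − x̄)²) and intradaily variability
  IV = n·Σ(x_i − x_{i−1})² / ((n−1)·Σ(x_i − x̄)²) on hourly means (p = 24);
- multiscale entropy shape: sample entropy H_SE = −ln(Aᵐ(r)/Bᵐ(r)) with
  m = 1, r = 0.1·STD at coarse-graining scales 1–5, summarized by the four
  coefficients of a least-squares cubic in the scale index (MSE(1) = cubic
  term … MSE(4) = constant);
- transfer-entropy shape: TE(X→Y) = Σ p(y_{i+t}, y_i, x_{i+t−τ})
  log₂[p(y_{i+t}|y_i, x_{i+t−τ}) / p(y_{i+t}|y_i)] in bits, k = l = t = 1,
  τ = 1…5, estimated with Darbellay–Vajda adaptive partitioning, in both
  directions, summarized by the same cubic-fit coefficients.

**Selection and classification.** Features are discretized into five states
at Mean + {−1, −0.5, +0.5, +1}·STD and ranked by incremental mRMR under the
Mutual-Information-Difference scheme; an RBF-kernel SVM
(K = exp(−‖u−v‖²/2σ²), σ = 4) is evaluated under 1000-repeat random-
subsampling two-fold cross-validation for HR-only, activity-only and fused
feature sets, with pooled-score ROC/AUC and Wilcoxon–Bonferroni group
screening.

## Worked example

```sh
actihr run --seed 3 --out runs/demo
```

simulates a calibrated cohort (16 cases of which 4 carry >10% injected
artifacts, 19 controls, 21 days each), preprocesses it, extracts the 36
features, and runs the three experiments (about 90 s on one CPU). The
report it prints ends with:

```
| feature set | k | accuracy % | sensitivity % | specificity % | AUC |
|---|---|---|---|---|---|
| hr | 1 | 100.0 | 100.0 | 100.0 | 1.000 |
| activity | 1 | 100.0 | 100.0 | 100.0 | 1.000 |
| fused | 1 | 100.0 | 100.0 | 100.0 | 1.000 |
```

The manifest records that exactly the four corrupted cases were rejected
(12 cases + 19 controls analyzed). Group means in the feature table land on
the generator's calibration targets — case mean HR ≈ 82 bpm vs control
≈ 76 bpm, case activity STD ≈ 0.07 vs control ≈ 0.14 — and `k` is the
mRMR prefix size with the best cross-validated accuracy. The synthetic
groups are deliberately well separated, so all three feature sets reach
ceiling accuracy here; the interesting outputs on real data are the
relative ordering of the three AUCs and the selected features. Equivalent
stage-by-stage commands: `actihr simulate`, `actihr preprocess`,
`actihr features`, `actihr classify` (see `--help`).

From Python:

```python
from actihr import RunConfig, run_pipeline
res = run_pipeline(RunConfig(seed=3, n_repeats=100), "runs/demo")
print(res.experiments["fused"].best.auc)
```

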