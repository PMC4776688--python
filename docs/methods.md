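# Methods

This note documents the models, estimators and design choices behind
`actihr`, the defaults that matter, and what the synthetic-data results do
and do not demonstrate.

## Preprocessing model

Both signals arrive as irregularly timestamped samples. The chain is:

1. **Gap flagging.** Any inter-sample span longer than 1.5× the nominal
   collection rate (15 min for HR, 7.5 min for activity) is a low-quality
   gap. We interpret the rule as invalidating the *span* — the resampler
   must not hold a value across it — rather than deleting the valid samples
   bounding it, which would discard exactly the information the rule
   protects.
2. **HR floor.** Samples strictly below 20 bpm are physiologically
   implausible and removed; exactly 20 bpm is retained. Removed samples
   accumulate into the subject's artifact fraction (denominator: raw sample
   count).
3–4. **Zero-order hold** onto exact 10-min (HR) and 5-min (activity)
   grids. A slot takes the most recent observation unless that observation
   is more than 1.5× the grid interval in the past or the slot falls
   strictly inside a flagged gap; such slots are explicitly missing (NaN).
5. **Linear down-sampling** of activity to the synchronous 10-min grid:
   each 10-min slot is the mean of the two 5-min slots it covers
   (slot-aligned pairing); missingness propagates.

**Day selection.** Days are calendar days from local midnight of the
subject's first recording day (the recordings carry no timezone; a single
implicit local clock is assumed). Each spanned day contributes a full
complement of slots, so partial edge days rank as mostly missing. The 10
days with the lowest missing fraction are retained, ties to the earlier
day; contiguity is not required, and the retained days are spliced and
treated as contiguous downstream (the standard actigraphy convention when
splicing best days). One set of days is selected per subject, ranking days
by the mean of the two signals' missing fractions. **Quality gate:**
subjects with artifact fraction or post-selection missing fraction above
10% (strictly) in either signal are rejected; exactly 10.0% passes.

## Feature families

All features are computed on the 10 retained days. Residual missing slots
are linearly interpolated (nearest value at the edges) before entropy and
transfer-entropy computation only; summary statistics and rest–activity
metrics skip missing slots.

**Summary statistics.** Mean, median, mode, sample STD (ddof = 1) and IQR.
The mode is computed after rounding to a resolution of 1 bpm (HR) or 0.01
(activity); ties go to the smallest value.

**Rest–activity metrics.** L5/M10 are window *sums* of native-resolution
slots of the mean daily profile (30/60 slots for HR at 10 min, 60/120 for
activity at 5 min) — the sum convention is what reproduces the published
magnitude of these quantities (a 65-bpm constant profile gives
L5 = 30 × 65 = 1950). Windows wrap circularly across midnight, ties to the
earliest start; missing profile slots are circularly interpolated before
the search so window sums are comparable across subjects.
RA = (M10 − L5)/(M10 + L5). IS and IV follow the classical non-parametric
convention on hourly means with p = 24 hourly bins; both are undefined
(NaN) for constant signals and are affine-invariant. For hourly white
noise IS ≈ 1/(number of days) and IV ≈ 2, which the tests verify by Monte
Carlo.

**Multiscale entropy.** Sample entropy −ln(Aᵐ(r)/Bᵐ(r)) with Chebyshev
template distance and both counts taken over the first N − m template
starts (self-matches excluded). Defaults m = 1 and r = 0.1 × sample STD;
r is computed once from the scale-1 series and held fixed across the five
coarse-graining scales (the standard multiscale protocol). The feature set
keeps the four descending-degree coefficients of a least-squares cubic in
the scale index, not the raw entropies; the constant term (MSE(4)) tracks
the overall entropy level, which is why it is the most informative of the
four. A profile with any undefined scale (no template matches) is flagged
and yields NaN coefficients, later median-imputed (below).

**Transfer entropy.** TE(X→Y) at history lengths k = l = 1, prediction lag
t = 1 and source lags τ = 1…5 on the synchronized 10-min grid, in bits.
Each margin is rank-transformed to (0, 1) to remove marginal-scale effects,
then the (y_{i+t}, y_i, x_{i+t−τ}) triples are partitioned by the
Darbellay–Vajda scheme: a cell splits at its marginal midpoints into 2³
subcells while a chi-squared test rejects within-cell uniformity at
α = 0.05, provided the expected count per subcell is at least 5; cells of
identical (tied-rank) points and depths beyond 60 stop unconditionally.
Cell probabilities are plug-in counts; the conditional terms use counts of
the cell's edges projected onto the (y_i, x), (y_{i+t}, y_i) and (y_i)
subspaces. Estimates require at least 500 complete triples (about 3.5 days
of 10-min data) or the feature is flagged unavailable. The estimator is
validated against the analytic 1-bit copy system and the independence null,
and its error decreases with sample size; a mild negative bias of order
0.01–0.05 bits remains at n ≈ 1400, which the cubic-fit summarization
tolerates. Both directions are computed: the HR feature column carries
TE(HR→activity) and the activity column TE(activity→HR).

## Feature selection and classification

Features are discretized into five states with edges at
μ + {−1, −0.5, +0.5, +1}σ over all subjects, boundary values to the upper
bin; zero-variance features collapse to the middle state with a warning.
mRMR ranking uses the Mutual-Information-Difference scheme with plug-in
discrete MI in bits, ties broken lexicographically on the feature name.
Flagged-unavailable features are imputed with the column median before
modeling.

The classifier is an RBF-kernel SVM with kernel width parameterized as
K = exp(−‖u−v‖²/(2σ²)), σ = 4 (sklearn gamma = 1/(2σ²) = 1/32) and cost
C = 1 (exposed in the config; the protocol leaves it unspecified).
Features are z-scored with training-half statistics so a shared σ is
meaningful across mixed-unit features. Evaluation is repeated random
subsampling: each of 1000 repeats draws a *stratified* 50/50 split
(unstratified halves of a 12-vs-19 cohort frequently lack a class) and
tests both halves in turn; accuracy, sensitivity (true-positive rate on
cases) and specificity (true-negative rate on controls) are averaged over
repeats, and a single ROC is built from the decision scores pooled across
all test folds with trapezoid AUC. Feature ranking happens once on the
full dataset before cross-validation — the dataset-level ranking is itself
a reported output — which optimistically biases the prefix accuracies;
the metrics file carries an explicit note to that effect. Group screening
uses the two-sided Wilcoxon rank-sum test (exact when the combined sample
is ≤ 25 and untied, normal approximation with tie correction otherwise)
with Bonferroni correction over all 36 features.

## Synthetic cohort generator

The generator emulates multi-week chest-patch recordings. Activity is a
rectified 24-h sinusoid wake envelope (rise around 08:00, per-day phase
jitter) scaling both a baseline day level and the probability of lognormal
activity bursts, plus a small near-zero night level, clipped to [0, 1].
HR is baseline + a 24-h sinusoid (acrophase mid-afternoon) + an
instantaneous gain times concurrent activity + AR(1) noise whose
coefficient is the profile's `mse_roughness`. The instantaneous
activity→HR gain gives a nonzero ground-truth transfer entropy in that
direction, which the coupling tests exploit; the AR(1) coefficient
controls how fast sample entropy decays across scales. Sampling times are
jittered Gaussian increments; corruption is contiguous dropouts plus HR
values drawn uniformly in [5, 19.5] bpm, with the injected fractions
recorded so tests can compare detected against injected corruption.

The packaged profiles (`profiles/default.yaml`, versioned) were calibrated
once by Monte-Carlo runs of the generator through the full preprocessing
chain against the published group-level targets and then frozen: control
mean HR ≈ 76 bpm / case ≈ 82 bpm, HR STD ≈ 14 bpm, control activity
STD ≈ 0.13 / case ≈ 0.08, with the case group's higher AR coefficient
producing the flatter entropy-by-scale profile. Profiles are stationary
over a recording — no medication or symptom dynamics — and there is no
between-subject parameter heterogeneity within a group, so subject-level
feature spreads are narrower than in a real cohort. Consequently the
synthetic groups are close to linearly separable and all three classifiers
sit at ceiling accuracy; passing tests demonstrate the machinery
(direction of contrasts, exact gate behavior, fusion not underperforming
either modality), not real-data effect sizes or error rates. Relative
amplitude is likewise higher than in real cohorts (~0.95 vs ~0.7) because
synthetic nights are more quiescent than human ones.

## Determinism and problem sizes

A single master seed fans out through `numpy.random.SeedSequence` spawning
to per-subject generation, corruption and per-experiment CV streams, so
stages are individually reproducible and whole-run manifests are
byte-identical across same-seed runs. Default demo sizes: 16 + 19 subjects,
21 recording days, 10 retained; the test suite uses 10–14 days and 10–50 CV
repeats for its end-to-end checks, and `scripts/acceptance.py` uses 300
repeats per (set, prefix) evaluation — sizes chosen to keep a full run on
one CPU in the minutes range while leaving every statistical check
well-resolved.

## Known limitations

- The TE estimator's marginal counts come from projected cell edges, not a
  separately adapted 2-D/1-D partition; this is the common simplification
  and is absorbed by the shape-coefficient summarization.
- IS/IV assume the spliced best days are contiguous; splicing introduces
  at most one artificial hour-to-hour transition per day boundary.
- The day boundary is local midnight of a single implicit clock; daylight
  saving and travel are not modelled.
- No ECG-level artifact detection: quality is defined entirely by the
  epoch-level rules above.
- No surrogate-data significance testing for TE, and no scale-dependent r
  or composite multiscale-entropy variants.
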