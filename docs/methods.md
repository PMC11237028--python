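# Methods

## Synthetic cohort generator

The generator emulates a 98-patient blood-cancer cohort described only by
marginal summaries: category counts for 16 demographic/history features,
means and SDs for 4 clinical vitals and 33 laboratory values, plus 8
features recorded so sparsely (>90% missing) that preprocessing discards
them. Because only marginals are published, features are generated
independently as truncated Gaussians, with one documented exception:
hematocrit is drawn conditionally on hemoglobin with correlation ρ = 0.9
(slope ρ·σ_Hct/σ_Hgb), which preserves Hct's published marginal moments
while reflecting the strong physiological Hgb–Hct link. Truncation bounds
are mean ± 4 SD clipped to physiological hard limits (pH ∈ [6.8, 7.8],
SpO₂ ≤ 100%, floors at or near zero for enzymes and counts). For strongly
skewed analytes near a floor (notably troponin T, mean 0.031 / SD 0.171
ng/mL) the truncated Gaussian is a deliberate simplification; tests
compare sample moments against the *truncated* distribution's theoretical
moments, not the nominal parameters.

Demographics use quota sampling at the reference size n = 98 (category
counts reproduced exactly, order shuffled) and proportional sampling at
any other n.

**Trajectories.** Daily values follow a stationary AR(1) centred on each
patient's baseline, with the feature's SD as marginal SD and lag-1
autocorrelation 0.7 by default (configurable); day 0 is the baseline
draw. AR(1) is the simplest stationary process with tunable persistence;
it does not model trends, circadian structure, or treatment responses.
Default horizon is T = 7 days — a desk-scale week of daily forecasting.

**Daily labels.** The ground-truth PRBC requirement is logistic in an
intercept-free linear risk score that rises (per reference SD) as Hgb
(weight 1.5), PaO₂ (0.8), systolic blood pressure (0.3) and platelets
(0.3) fall below their cohort means, and as pH falls below 7.40 toward
acidosis (0.8, one-sided); alkalosis carries no extra risk, so risk is
monotone in the acidosis distance. The intercept −5.21 was calibrated
once by bisection on a 20,000-patient simulated cohort (seed 12345) to a
daily positive prevalence of 7%, matching the reference training-set
label rate; `calibrate_intercept()` re-derives it. Two auxiliary modes
exist for exact tests: a deterministic *threshold* mode labelling a day
positive when the intercept-free score exceeds 1.0 (chosen so that a
clearly anemic-hypoxemic-acidotic day (Hgb 7.2, PaO₂ 42, pH 7.25) alarms
and a healthy extreme does not), and a *trend* mode labelling a day
positive when hemoglobin fell by more than 1 g/dL since the previous day
— a purely sequential signal used to contrast sequence models with
static ones.

**Missingness** is missing-completely-at-random per cell at each
feature's rate (0.95 for the 8 excluded features; 0.55–0.60 for the three
majority-missing labs that acquire presence indicators; 2–5% elsewhere).
Missing cells are NaN/None, never numeric sentinels. Real-world
missingness is informative; MCAR is a known simplification, so passing
tests show pipeline correctness, not robustness to informative dropout.

**What passing tests do not show.** The generator reproduces published
marginals, not the real joint distribution, temporal physiology, or
treatment feedback; benchmark accuracies on synthetic cohorts are
properties of the generator's label model and are not comparable to
accuracies on the private clinical data.

## Preprocessing

Stage order is fixed: exclusion (> 90% missing, strict) → presence
indicators (> 50% missing, strict; 0 = missing, 1 = present) → median
imputation over observed cells → encodings → first-timepoint anchoring →
normalization. "Normalize" is implemented as z-scoring with
training-split statistics stored for held-out reuse (min–max by flag),
robust to the very different units across features. Encodings: sex
Male→1/Female→2; cancer type ALL/AML/CLL/CML→1–4; history and behaviour
flags No→0/Yes→1; troponin T binarized at 0.014 ng/mL (a conventional
assay positivity cutoff; configurable). Anchoring left-aligns heart rate
and blood pressures to each patient's first recorded day; since the
pipeline imputes before anchoring, the driver captures leading-missing
runs beforehand. The shifted series is tail-padded with the last recorded
value so all series keep equal length (removing days would desynchronize
features). The full pipeline is idempotent.

Collinearity screening uses Pearson correlation matrices over patient
baselines (day-0 values) per feature group, with an optional heatmap
export; feature selection itself is an expert judgment and is not
automated here.

## Fuzzy inference core

Partitions are triangular, normal, complete and consistent; interior MF
feet coincide with neighbouring centers, giving an exact partition of
unity between extreme centers, and extreme MFs become shoulders
(membership 1 beyond their center) so completeness holds across the whole
universe. The default PaO₂ centers {30, 90} lie outside the stated
universe [40, 80]; the shoulders extend the effective support to the
center span, keeping the printed centers as the operative quantities. The
pH partition's three MFs cover a narrow band of [6.3, 7.8] the same way.
Linguistic labels are attached to ascending centers in their published
order; the label–center pairing does not enter the arithmetic.

Inference is the FBF expansion f(z) = Σ dᵢθᵢ with dᵢ the product of
antecedent memberships. The normalized form Σdᵢθᵢ/Σdᵢ is the default: it
is well-defined for incomplete learned rule bases and bounded by the
output centers [0.25, 0.75]; the literal unnormalized sum is available by
flag and coincides with it under a complete grid rule base (the FBFs then
form a partition of unity). An input covered by no rule raises an
explicit uncovered-input error.

Rule learning is Wang–Mendel table lookup: per sample, the
max-membership MF of each input and of the output (ties → lower index),
degree = product of those memberships, one max-degree rule per antecedent
cell (ties → lower consequent). Inputs outside the universe are clipped
with a warning. Because the lookup only creates rules for visited cells,
`complete_rule_base` can fill the remaining cells with the consequent of
the nearest learned cell (Manhattan distance in MF-index space, degree 0)
— used by the evaluation harness so noisy test points are always covered.

Swarm evaluation partitions the rule base across agents; each agent
returns (Σdᵢθᵢ, Σdᵢ) over its rules and the aggregate is exactly the
centralized result, for any assignment that covers each rule once. The
alarm fires iff f(z) < 0.5 (midpoint of the output centers;
configurable); the boundary value itself maps to Normal. Alarm messages
are structured JSON records (value, label, threshold, input snapshot,
timestamp) ready for gateway delivery; transport is out of scope.

## Noise robustness

AWGN is added at SNRs of 30, 10 and 5 dB with noise variance
σ² = Var(signal)/10^(SNR/10) per feature. Signal power is the variance
(AC power), not the mean square: offsets such as pH ≈ 7.35 would
otherwise make nominal SNRs physically meaningless. Each evaluation run
splits patients 70/30 into train/test, learns rules on training days, and
scores RMSE of f(z) on test days against the ground-truth state encoded
at the output centers (label 1 → 0.25, label 0 → 0.75, so RMSE is
commensurate with f's range); noise is applied to test inputs only — a
measurement-noise reading. Within a run all conditions share one noise
realization scaled to each SNR (common random numbers), so condition
contrasts are not masked by independent draws. Reported RMSEs are means
over 10 runs by default (20 in the monotonicity tests).

At 30 dB the noise SD is ~3% of the signal SD and its expected effect on
RMSE is of order 10⁻⁴ — smaller than run-to-run variation, and near
kinks of the piecewise-linear f tiny noise can even be marginally
error-reducing. The degradation tests therefore check the *expected*
ordering clean ≤ 30 dB ≤ 10 dB ≤ 5 dB via paired differences with a
two-standard-error allowance, rather than strict sample-mean inequality.

## Benchmark harness

Six models are compared under patient-level 5-fold cross-validation
(no patient contributes days to both sides of a fold), day-level accuracy
pooled over held-out days, 10 repeated runs with re-drawn seeded folds,
and identical fold assignments across models so per-run accuracies are
paired. The recurrent entries are a 2-layer (bi)LSTM with 128 hidden
units, log-softmax head, initial learning rate 0.01, and at most 100
epochs of full-batch Adam — implemented directly in numpy with
backpropagation through time, gradient-checked against central
differences. Static baselines (multilayer perceptron, AdaBoost, bagged
decision trees, bagged k-nearest-neighbours) are scikit-learn estimators
with library defaults, consuming one day's feature vector per sample —
the flattening is deterministic and makes day-to-day dynamics invisible
to them by construction, which is exactly the contrast the trend-label
cohort probes. Fixed epoch budgets and final-epoch weights are used (no
early stopping) for reproducibility. Test-suite runs use reduced sizes
(16 hidden units, 60 epochs, 40 patients × 10 days) chosen as the
smallest configuration where the recurrent model's advantage on
trend-dependent labels is stable.

## Numerical choices and degenerate inputs

- Argmax ties in rule learning and fold assignment break deterministically
  (lower index); all randomness flows through numpy Generators seeded from
  user-supplied integers.
- Zero-variance features: normalization scales by 1 with a warning;
  AWGN at finite SNR raises (noise scale undefined).
- Median of an entirely-missing feature raises, naming the feature.
- All-missing anchored series raise; out-of-range observed values on file
  read are logged, not rejected.
- Cohort regeneration with identical (schema, n, seed) is bit-identical.

## Known limitations

- Independent marginals (except Hgb–Hct) understate real covariance;
  correlation screens on synthetic data are near-diagonal by construction.
- The published PaO₂ mean (34.54 mmHg) sits below the fuzzy universe
  [40, 80]; the generator follows the published summary and the fuzzy
  module follows the published universe, so many synthetic days fall in
  the lowest PaO₂ cell and are clipped during rule learning. The
  discrepancy is inherited from the source material and intentionally
  not reconciled.
- MCAR missingness, AR(1) dynamics and logistic labels are modelling
  conveniences; none is a validated clinical model.
- RMSE and accuracy values on synthetic cohorts characterize the method's
  mechanics, not clinical performance.
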