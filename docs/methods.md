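# Methods

## Setting and notation

`errkit` targets studies in which a continuous exposure of interest X
(typically a long-term "usual" level, e.g. habitual nutrient intake or
blood pressure) cannot be observed; the data carry an error-prone
measurement W1 for everyone and a repeat measurement W2 — with error from
the same distribution as W1's — for a subset. The outcome Y is binary and
the target parameter is the exposure log odds ratio β in

    logit P(Y = 1 | X, Z) = β0 + β X + γ'Z,

with error-free adjustment covariates Z. Fitting this model with W1 in
place of X (the naive analysis) gives a biased β*; the package's job is to
undo that bias under an explicit model for the measurement error.

### Error models

* **Classical**: W_ij = X_i + ε_ij with mean-zero errors of constant
  variance σ²_ε, independent of X, Z, Y and of each other. Under a linear
  association this attenuates β by the regression dilution ratio (RDR)
  λ = var(X|Z) / var(W1|Z).
* **Systematic**: W_ij = ψ + θ X_i + ε_ij, corr(ε_i1, ε_i2) = ρ. θ ≠ 1
  means the error scales with true exposure; ρ > 0 encodes person-specific
  error shared by repeats. (ψ, θ, ρ) are not identifiable from repeated
  measurements and enter only as sensitivity parameters.
* **Heteroscedastic (multiplicative lognormal)**: W_ij = X_i v_ij with
  log v_ij ~ N(−σ²_u/2, σ²_u), so E(W|X) = X on the natural scale and the
  log-scale data follow a classical model with a constant shift.
* **Differential**: any of the above with (ψ_y, θ_y, ρ_y, σ_εy) depending
  on the realized outcome — e.g. recall bias in cases.

## Correction methods

### Regression calibration (RC)

Replace X by E(X | W1, Z) in the outcome model. With repeats, the
calibration model is estimated by OLS of W2 on (W1, Z) over the repeat
subset; its W1 slope λ̂ estimates the RDR, and the corrected estimate is
β̂ = β̂*/λ̂ — exactly the same number as refitting the logistic model on
the predictions μ̂ + λ̂ W1 + δ̂'Z (the package tests this equivalence to
1e-8). Two standard errors are reported: (a) se*/λ̂, treating λ̂ as known,
and (b) the first-order delta-method variance

    var(β̂) = var(β̂*)/λ̂² + β̂*² var(λ̂)/λ̂⁴,

treating β̂* and λ̂ as independent (they derive from the outcome model and
the repeat regression respectively; the neglected covariance is checked
against a whole-pipeline bootstrap in the test suite, which agrees within
15%).

### Probit refinement

The ratio correction is only approximate for logistic models. Using the
probit approximation logistic_cdf(x) ≈ Φ(l·x), marginalizing the outcome
model over X | W1, Z gives β* = βλ/√(1 + l²β²σ²_{X|W}), which inverts to

    β̂ = β̂* / sqrt(λ̂² − l² β̂*² σ̂²_{X|W}),

with σ̂²_{X|W} = λ̂(1−λ̂)·var̂(W1|Z) (the classical-model identity;
var̂(W1|Z) is the residual variance of W1 on Z over all subjects). The
scale constant l is computed once by minimizing the sup-norm distance
between the logistic cdf and Φ(l·x) over a dense grid on ±10
(l ≈ 0.5876, i.e. 1/1.702) and cached. If the discriminant is not
positive — an enormous effect or tiny λ̂ — the function warns and falls
back to the plain ratio. The inversion is validated against a Monte-Carlo
marginalization oracle in the test suite. Its SE uses a numerical
(central-difference) delta method in (β̂*, λ̂) rather than a closed form.

### Sensitivity analysis for systematic error

Under the systematic model, cov(X, W1|Z) = θ·var(X|Z) and the repeat
regression slope estimates λ* = (θ²var(X|Z) + ρσ²_ε)/var(W1|Z), so the
RDR is recovered for assumed (θ, ρ) as

    λ̂ = (λ̂* − ρ) / (θ (1 − ρ)),

and β̂ = β̂*/λ̂ as before. ψ never enters. θ = 1, ρ = 0 reproduces the
classical correction exactly. λ̂* ≤ ρ is a hard error (the assumed error
correlation would explain all of the repeat agreement). `sensitivity_grid`
evaluates a cartesian grid of (θ, ρ) values; the delta-method variance
propagates var(λ̂*) through dλ/dλ* = 1/(θ(1−ρ)). The variance of λ̂* is
taken as the OLS slope variance.

### Multivariate RC

With K jointly mismeasured exposures, each E(X_k | W1-vector, Z) is
estimated by OLS of that exposure's repeat on all first measurements and
Z over the subset with repeats for every exposure; the logistic model is
refit on the K predictions. Variance is by stratified bootstrap only.

### Lognormal (heteroscedastic) RC

When a linear effect of the *natural-scale* exposure is wanted under
multiplicative error, joint lognormality of (X, W1) given Z yields a
closed-form conditional mean. Writing var̂(log W1|Z) for the log-scale
residual variance and λ̂_log for the slope of log W2 on log W1 (and Z):

    σ̂²_u        = (1 − λ̂_log) · var̂(log W1|Z)
    var̂(log X)  = var̂(log W1|Z) − σ̂²_u
    μ̂_{logX|·}  = Ê(log W1|Z) + σ̂²_u/2 + λ̂_log (log W1 − Ê(log W1|Z))
    Ê(X|W1,Z)   = exp{ μ̂_{logX|·} + ½ var̂(log X)(1 − λ̂_log) }

(the +σ̂²_u/2 shift comes from natural-scale unbiasedness E(W|X) = X).
The logistic model refit on Ê(X|W1,Z) estimates the natural-scale β; SEs
require the whole-pipeline bootstrap. λ̂_log outside (0, 1] is a model
contradiction and errors out. The conditional-mean formula is validated
against binned Monte-Carlo conditional means (10⁶ draws, < 2% relative
deviation) in the test suite.

A diagnostic for this error type plots the per-person SD of {W1, W2}
against the per-person mean: a positive sd-on-mean OLS slope indicates
error variance growing with exposure level.

### Moment reconstruction (MR)

MR transforms W1 so that the first two joint moments with Y match those
of X:

    X_MR = Ê(X|Y,Z) + (W1 − Ê(W1|Y,Z)) · sqrt(var̂(X|Y,Z)/var̂(W1|Y,Z)),

and fits the outcome model on X_MR. Because the transform conditions on Y,
MR stays valid under differential error, where RC does not. The needed
moments come from stratum-wise estimation: E(W1|Y,Z) by per-stratum OLS on
Z over all subjects; var(W1|Y,Z) as its residual variance;
cov(W1,W2|Y,Z) as the cross-product of Z-residuals over the repeat subset
(denominator n − k − 1); then

    σ̂²_εy      = [var̂(W1|y,Z) − cov̂(W1,W2|y,Z)] / (1 − ρ_y)
    var̂(X|y,Z) = [cov̂(W1,W2|y,Z) − ρ_y var̂(W1|y,Z)] / [θ_y²(1 − ρ_y)]
    Ê(X|y,Z)   = [Ê(W1|y,Z) − ψ_y] / θ_y.

(ψ_y, θ_y, ρ_y) must be supplied; (0, 1, 0) recovers the non-differential
classical case. Negative implied variances abort with a model-contradiction
error rather than being truncated — truncation would hide that the assumed
error model cannot hold for the data. Repeats are required in both outcome
strata.

### Multiple imputation (MI)

MI draws the unobserved X from its Gaussian conditional given all observed
data. For subjects without a repeat,

    E(X|W1,Y,Z)   = Ê(X|Y,Z) + b_y (W1 − Ê(W1|Y,Z)),
    b_y           = θ_y var̂(X|Y,Z) / var̂(W1|Y,Z),
    var(X|W1,Y,Z) = var̂(X|Y,Z) − θ_y² var̂(X|Y,Z)² / var̂(W1|Y,Z);

for subjects with a repeat the conditioning is on (W1, W2) jointly, with
cov(X, W) = θ_y v (1, 1)' and the 2×2 W-covariance built from (θ_y, ρ_y,
v, σ²_εy) — standard multivariate-normal conditioning, tested to 1e-10
against brute-force block inversion. Conditioning on the repeat always
tightens the conditional variance. M imputed datasets (default M = 20)
each get a logistic fit, pooled by Rubin's rules: pooled = mean estimate,
T = A + (1 + 1/M)B with A the mean within-imputation variance and B the
between-imputation sample variance. Confidence intervals use the normal
reference rather than Barnard–Rubin degrees of freedom — a deliberate
simplification appropriate for the study sizes targeted here. Rubin's T
ignores uncertainty in the estimated error moments; the fully propagated
SE bootstraps the whole chain, re-estimating moments and re-imputing (with
a fresh sub-seed) in every resample.

### Categorized exposures

Quantile grouping of a mismeasured exposure misclassifies subjects near
the cutpoints, and does so differentially even when the underlying error
is non-differential. Three corrections:

* **MacMahon's method**: per-group naive log ORs (groups formed on W1,
  group 1 the reference) are plotted against the mean of W2 among repeat
  subjects in each group — an unbiased usual-exposure estimate because
  W2's error is independent of the W1-based grouping. W2 alone (not
  (W1+W2)/2) is used for exactly that independence. Assumes classical
  error and an (approximately) linear association.
* **Impute-then-categorize**: categorize X_MR, or categorize within each
  MI-imputed dataset and pool each group's log OR by Rubin's rules (the
  pooling rule for grouped MI is not standardized; per-coefficient Rubin
  pooling is this package's choice).
* **Quantile-trend correction**: for a linear trend across Q quantile
  groups of a normal exposure, the naive per-group trend β*ᴳ is attenuated
  by corr(X, W1|Z), not by λ, so

      β̂ᴳ = β̂*ᴳ · sqrt((1 − ρ)/(λ̂* − ρ)),

  which at ρ = 0 is β̂*ᴳ/√λ̂*. θ cancels (corr² = θλ = (λ*−ρ)/(1−ρ)), so
  only ρ must be assumed — the function deliberately takes no θ argument.
  The correction factor is strictly smaller than the continuous-scale
  1/λ̂ whenever λ̂* < 1. Valid only for quantile groups (not fixed
  cutpoints) and equally for SD-standardized exposures.

Quantile assignment uses rank-based (empirical type-7) cutting with ties
broken by stable input order, so group sizes differ by at most one; fewer
distinct values than groups is an error reporting the tie mass.

### Bootstrap

`bootstrap_correct` resamples subjects with replacement within strata
defined by (outcome, repeat availability), preserving the case/control
split and repeat-subset size, and re-runs the complete estimator —
including re-estimation of calibration or moment parameters — per
resample. The default is appropriate for cohort and frequency-matched
case-control designs; other designs can pass their own resampling by
pre-stratifying. MI estimators are re-seeded per resample through a nested
seed protocol. An estimator failure rate above 10% of resamples aborts
with diagnostics. At least 50 resamples are required for an SE, 999 for
percentile intervals.

## Synthetic data generator

`simulate.generate_study` draws Z (independent standard normal or
Bernoulli(0.5) columns — the covariate law is a package default, chosen as
the simplest exchangeable design, not dictated by the methods), X normal
or lognormal given Z, Y from the logistic model, and then the error model
conditional on the realized Y, so differential error is generated the way
it is defined. Correlated repeat errors use the shared-person-effect
decomposition ε_ij = b_i + e_ij (var b = ρσ², var e = (1−ρ)σ²), which
restricts ρ to [0, 1) — negative within-person error correlation is
rejected rather than silently mishandled. Case-control samples are drawn
without replacement from a super-cohort of size max(n, 20(n_cases +
n_controls)). All randomness flows from one seed through named
SeedSequence streams, so each component (covariates, exposure, outcome,
errors, repeat selection, sampling) is independently reproducible.

Canonical scenarios (fixed parameter sets used throughout the tests):

* `classical_recovery` — σ_X = σ_ε = 1 (λ = 0.5), β = 0.3, β0 = −1
  (event fraction ≈ 0.27), n = 5000, 50% with repeats.
* `differential_shift` — as above with a case-only mean shift ψ_1 = 0.5σ_X.
* `systematic_person_effect` — ψ = 0.5, θ = 0.8, ρ = 0.3.
* `lognormal_heteroscedastic` — lognormal X (log-scale SD 0.5),
  multiplicative error σ_u = 0.4, natural-scale β = 0.2.
* `case_control_classical` — 305 cases / 1222 controls sampled from a
  super-cohort, 26% with repeats.

What the generator does *not* emulate: real dietary data's zero inflation,
skewness beyond lognormal, time trends between measurement occasions,
matched-set sampling, and missingness in Z or W1. Passing parameter-recovery
tests therefore demonstrates correctness of the estimators under their
stated assumptions, not robustness to these real-data features.

## Validation design and problem sizes

The test suite validates each estimator by parameter recovery against the
generating truth, and each reconstructed formula against an independent
oracle (brute-force multivariate-normal conditioning, Monte-Carlo
marginalization, binned conditional means, numerical delta method,
whole-pipeline bootstrap). The replication studies use 500 cohorts of
n = 5000 for the classical operating characteristics (bias of naive/RC/
MR/MI, delta-method CI coverage) and 150 cohorts for the differential
contrast; these sizes put the Monte-Carlo SE of a mean at ≈ 0.002–0.004,
well inside the tested bias bands. The efficiency comparison (RC vs MR/MI
propagated SEs) uses a 10% repeat share, where the moment-estimation
overhead of the outcome-conditional methods is material.

## Numerical choices and edge cases

* Logistic fits: Newton-Raphson (statsmodels), relative tolerance 1e-10,
  100 iterations; non-convergence, rank deficiency, separation, or wildly
  diverging coefficients raise `FitError` — never silent estimates.
* λ̂ ≤ 0, λ̂* ≤ ρ, λ̂_log outside (0, 1], and negative implied variances
  are hard errors with diagnostic messages, not clamps or sign flips.
* The σ_ε = 0 degenerate case makes the repeat-pair covariance exactly
  singular but consistent; MI then imputes (W1 − ψ_y)/θ_y exactly (solved
  by pseudo-inverse with a consistency check). An inconsistent singular
  covariance still errors.
* Dataset text round trips are bit-exact (`%.17g` on write, round-trip
  float parsing on read); missing W2 is an empty field, never a sentinel.
* Complete cases on Z are required at construction; missing W1 is
  rejected with a count.

## Known limitations

* RC for logistic models is approximate even after the probit refinement;
  for very large |β| the refinement's discriminant can fail, triggering
  the documented fallback.
* The delta-method variance ignores cov(β̂*, λ̂) and the estimation error
  of var̂(W1|Z); the bootstrap is the reference when this matters.
* MR/MI here are univariate in the error-prone exposure; multivariate
  error is handled only by RC.
* Matched-set (conditional logistic) analysis is approximated by
  unconditional logistic regression with the matching variables in Z.
* The quantile-trend correction assumes normality of (X, W1) and a linear
  trend; it does not apply to fixed-cutpoint categories.
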