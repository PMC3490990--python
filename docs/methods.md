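# Methods

## The model

The DOC-SVM is a linear scorer f(x) = w·x + b trained on

    ½‖w‖² + C₁ Σᵢ max(0, 1 − ỹᵢ f(xᵢ)) + C₂ Σᵢ (f(xᵢ) − yᵢ)²

with two codings of the same binary outcome: the hinge term uses
ỹ ∈ {−1, +1} (margin convention) and the squared term uses y ∈ {0, 1}
(probability convention). This dual coding is deliberate: the squared loss
is then the summed Brier score of the raw output, so its minimization pulls
f(x) onto the probability scale, and probabilities are read off by clipping
f(x) to [0, 1]. An exposed alternative would be to Platt-rescale DOC-SVM
outputs, but clipping is the default because the squared term is what the
objective already optimizes on that scale. C₂ = 0 recovers the plain
soft-margin SVM; the reduction is exact, down to identical optimizer
trajectories under a shared configuration, and is tested as such.

Why the joint objective targets both goals: the Brier score decomposes over
groups of identical predictions s (group size nₛ, positive fraction ρₛ) as

    Brier = CAL + REF,
    CAL = (1/N) Σₛ nₛ (s − ρₛ)²,   REF = (1/N) Σₛ nₛ ρₛ(1 − ρₛ).

CAL is zero exactly when each prediction value matches its group's event
rate (calibration); REF measures group impurity and connects to ranking:
the package implements the lower bound

    AUC ≥ 1 − (N² / (2 N₊ N₋)) · REF,

tight for the uninformative all-½ balanced sample, and the upper bound

    1 − AUC ≤ mean-hinge / (π(1 − π)),    π = N₊/N.

Both constants are the package's own reconstructions of the underlying
inequalities; they are verified empirically rather than cited — property
tests check them against brute-force pair counting on thousands of random
instances (the refinement bound under concordant between-group ordering,
where it is guaranteed; the hinge bound unconditionally).

## Measurement conventions

* **AUC** is computed through midranks (ties count ½), making the
  Mann–Whitney form and the trapezoidal area under the step ROC curve agree
  to machine precision; tied scores collapse into a single ROC step whose
  trapezoid is exactly the half credit. Single-class inputs raise an
  explicit error, never NaN.
* **Brier grouping** uses exact score equality after rounding to 12
  decimals. The decomposition is defined over discrete score values;
  with continuous scores every group is a singleton (REF = 0, CAL = Brier),
  which is still a valid decomposition — rounding only stabilizes grouping
  against float jitter.
* **Hosmer–Lemeshow.** Scheme H bins scores into g equal-width intervals
  ([0, 0.1), …, [0.9, 1] at the default g = 10); scheme C uses quantile
  edges of the score distribution with duplicate edges dropped, so tied
  scores always share a bin and bins hold approximately equal counts. Per
  bin the statistic accumulates (O − E)² / (E(1 − E/n)) with E the sum of
  predicted scores; the reference distribution is chi-square with g − 2
  degrees of freedom, g counting retained bins (empty bins are dropped).
  The 0.1-level critical value at ten bins is therefore the upper-0.1
  quantile of χ²₈ = 13.36. Degenerate bins (E = 0 or E = n): if the
  numerator is also zero the bin contributes 0 and is retained; otherwise it
  is merged with its neighbor toward the center, which avoids division by
  zero while preserving counts. If fewer than three bins remain, the
  statistic is still reported but the p-value is NaN (no degrees of freedom
  left); requesting g < 3 up front is an error. The fit threshold is applied
  to the p-value (reject calibration when p ≤ 0.1); reports carry both the
  statistic and the p-value so the threshold can be applied either way.
* **DeLong's variance** is used for the correlated-AUC z-test (the specific
  variance estimator for comparing two AUCs measured on the same
  observations); identical placements give z = 0, p = 1 by convention.
* **Threshold metrics** default to an operating point of 0.5 on the
  probability scale; the F-score is reported as 0 with a warning flag when
  both the predicted-positive and actual-positive sets are empty.

## Optimization

Training is deterministic full-batch subgradient descent from a zero start,
with the best iterate (lowest recorded objective) returned. The step at
iteration t is

    η_t = η₀ / (L · (1 + t·decay)),   η₀ = 0.1, decay = 0.01,

where L = 1 + C₁·R + 2·C₂·(R² + 1) and R is the mean row norm of the
(optionally z-scored) features. The objective sums losses over examples, so
its curvature grows with the penalties; the L factor keeps the step
commensurate across penalty scales — without it large C₂ diverges at any
fixed η₀. Subgradients are divided by N so the step is also insensitive to
sample size. The stopping rule is relative objective change below 1e−8
(cap 2000 iterations); pure-hinge objectives oscillate at the subgradient
kink and may hit the cap, in which case the best iterate is returned with a
warning flag rather than an exception. Features are z-scored by default and
the standardizer is stored in the model for test-time reuse; the bias is
never regularized.

Platt scaling fits P(y=1|f) = 1/(1 + exp(Af + B)) by BFGS on the Bernoulli
likelihood with the smoothed targets t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2);
constant scores fall back to A = 0 with B set by the smoothed prevalence.
Platt parameters are fit on the same training data that produced the scores,
in every context (no nested held-out split inside cross-validation); this
slightly optimistic choice is simple and deterministic, and the bias is
immaterial at the sample sizes used here. The logistic baseline is fit by
L-BFGS on the L2-penalized log-loss (bias unregularized) and cross-checked
against an independent reference implementation.

## Model selection and comparison

Cross-validation is stratified k-fold (default k = 10) over a log-spaced
penalty grid, 10^−3 … 10^3 with 7 points per penalty. The default selection
criterion is minimal mean Brier score — it captures both calibration and
refinement through the decomposition — with "auc" and "hlc_p" exposed as
alternatives; ties break toward smaller C₂ then smaller C₁ (prefer the less
constrained model only when it measurably helps). Folds that would leave a
training side single-class are re-drawn up to ten times. The repeated-split
protocol draws 30 stratified train/test partitions by default and records
AUC, F-score, sensitivity, specificity, Brier score and the HL-C p-value per
split and model; one-tailed paired t-tests compare models across splits
(identical vectors give p = 0.5 by convention; a constant nonzero difference
gives p = 0 or 1 by sign). Feature screening ranks by absolute Welch t with
a 1e−12 variance floor and index-order tie-breaks.

## Synthetic data: what it emulates and what it does not

* `gen_triangular_beta` draws labels Bernoulli(prior) and scores from the
  complementary triangular pair — density 2s for positives, 2(1−s) for
  negatives — realized exactly as the max and min of a uniform pair (the
  order statistics of U(0,1)²). At prior ½ the score marginal is uniform and
  P(y=1|s) = s: perfectly calibrated by construction, with population AUC
  exactly 5/6 (∫ 2s(2s−s²) ds = 5/6). This is the classical ceiling on
  discrimination under non-trivial perfect calibration.
* `shrink_scores` divides scores by a factor (default 10): the canonical
  counterexample separating the two goals — every rank-based quantity is
  untouched, Brier and HL degrade strictly on any sample with positives.
* `gen_gaussian_classes` draws spherical unit-variance Gaussians with class
  means ±δ/2 on the first axis. The Bayes posterior is logistic in x₁ and
  recorded as the sample's scores, with analytic AUC Φ(δ/√2) — giving
  closed-form recovery targets for both the metrics and the learners.
* `gen_grouped_bins` emits a few discrete score values, each label drawn at
  its own score: calibration without discrimination, the mirror image of
  score shrinkage, and the fixture for the calibration-pull property (with
  one-hot group features, large C₂/C₁ drives each group's predicted
  probability to its positive fraction; verified within 0.02 at N = 2000).
* `tradeoff_sweep` splits a feature sample in half (stratified), trains a
  DOC-SVM per C₂ at fixed C₁ and reports held-out AUC, HL-C and Brier. The
  study condition for the tradeoff curve is n = 600, d = 5, δ = 2, C₁ = 1,
  C₂ ∈ 10^−3 … 10^3 (7 log points): at this power the held-out HL-C p-value
  rises from ≈0 (hinge-dominated, miscalibrated) to a genuine interior peak
  (p up to ≈0.4) and falls again as the ridge-dominated linear probability
  model's own misfit to the logistic truth takes over, while AUC keeps
  rising toward the discrimination-dominated end. At much larger separations
  or test sizes the HL test's power drives all p-values toward zero and the
  peak location becomes numerically meaningless, so the condition above is
  the one the tradeoff test asserts (an interior maximum in ≥ 8 of 10
  seeds).

None of the generators emulate gene-expression data: there is no microarray
noise model, no feature correlation structure, and dimensionality is small.
Passing tests demonstrate the mathematical identities, bounds and tradeoff
mechanics — not performance on real transcriptomic cohorts, where feature
selection, preprocessing and cohort shift dominate.

## Numerical choices and edge cases

* All generators take an integer seed and are bit-reproducible.
* Labels may arrive as {0,1}, {−1,+1} or two string levels (mapped by sorted
  order); missing or malformed feature cells fail loudly with row/column.
* Scores outside [0,1] are a precondition error for calibration metrics,
  never silently clipped; ranking metrics accept any real scale.
* Problem sizes in the test suite (10⁶ Monte-Carlo draws for the
  triangular-beta concordance, 1000 random instances per bound suite,
  10 seeds for the tradeoff curve) were chosen so each suite completes in
  seconds while leaving Monte-Carlo error well inside the asserted
  tolerances.

## Known limitations

Linear scorers only — no kernels, no multiclass; clipping makes the
probability map piecewise-linear, so a DOC-SVM cannot represent a logistic
posterior exactly (visible as residual HL misfit at high power); the HL-C
quantile binning can produce unequal bin sizes under heavy score ties; the
subgradient method is first-order and the hinge-only limit converges slowly
near the optimum (mitigated by best-iterate return).
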