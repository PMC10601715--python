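# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Observation model and effect sizes

One observation is an independent control-vs-plastic comparison reporting
group means, SDs, and replicate counts. Observations are treated as
independent: no within-study covariance is modeled, because the
per-observation lnRR variance formula is the only uncertainty description
available at this level of data extraction, and screening criteria for
this literature minimize non-independence upstream.

- `lnrr(x̄_t, x̄_c)` requires strictly positive means; non-positive means
  make a ratio undefined, so such rows are excluded with a logged reason
  rather than offset-shifted (silent shifts bias effect sizes).
- The variance `v = s_t²/(n_t x̄_t²) + s_c²/(n_c x̄_c²)` is the delta-method
  variance of a log ratio of independent group means.
- **SD imputation.** Missing SDs are replaced by (mean CV) × (reported
  mean). The CV pool is all complete control/treatment groups sharing the
  record's parameter name; below a minimum pool size (default 3 CVs) the
  dataset-wide pool is used. Parameter-local pools respect the fact that
  assay CVs differ systematically between, say, enzyme activities and OTU
  counts. Imputed records carry a flag that propagates to output tables.
- **Ordination ratios.** Within- and between-group dispersion use the mean
  of pairwise Euclidean distances on the first two ordination axes (not
  centroid distances); `lnRRb = ln(D̄_t/D̄_c)` and
  `lnRRs = ln(D̄_b/(D̄_c + D̄_t))`. Both are invariant to a joint rescaling
  of coordinates, so the arbitrary axis scaling of digitized ordination
  plots cancels. The structure ratio's denominator uses the plain sum
  D̄_c + D̄_t; using the average of the two dispersions instead would only
  shift lnRRs by ln 2 and is left to sensitivity analyses.
- **Functionality.** Pooled soil functionality aggregates the lnRRs of the
  configured indicator list (default: soil respiration, FDA hydrolysis,
  C-/N-/P-acquisition enzymes, oxidative enzymes) with no direction
  harmonization: an activity indicator's sign is meaningful as-is, and
  flipping signs would presuppose which direction is "good". The list is
  user-overridable.

## Random-effects pooling and subgroups

Effects follow e_i ~ N(μ, v_i + τ²). τ² is estimated by REML (bounded
scalar optimization of the restricted likelihood, truncated at zero) or by
the closed-form DerSimonian–Laird moment estimator; REML is the default as
the modern standard, DL serves as a fast independent cross-check (one test
validates REML against R's metafor on a frozen dataset). Pooling uses
w_i = 1/(v_i + τ²), a normal-quantile CI by default (a t option exists),
and the CI-excludes-zero significance rule. With τ² = 0 this reduces
algebraically to fixed-effects inverse-variance weighting, which a test
asserts exactly.

Subgroup (categorical mixed-effects) analysis estimates a common τ² from
level-centered residuals, then partitions Q_total (against the overall
weighted mean) into within-level sums and the between-group Qm; Qm is
χ²(levels − 1) under homogeneity, and the partition is additive by
construction. Levels need **more than** `min_n = 5` observations (the
strict reading of the inclusion rule; configurable). Raw p-values are
reported; a Benjamini–Hochberg helper exists but is off by default to
match common practice in this literature.

## Dose–response cascade

Candidates on identical data: unweighted OLS, weighted least squares with
meta-analytic weights 1/(v + τ²), and a penalized B-spline GAM (statsmodels
`GLMGam`, default basis df 10, cubic). The smoothing penalty is selected by
GCV on a 23-point log grid spanning 1e-4–1e7; AIC is then computed once at
the selected fit, with parameter count = effective df + 1 (scale). All
AICs come from the same weighted Gaussian log-likelihood with weights
normalized to sum to n, so candidates sharing weights are comparable;
selection never compares fits with different weights. The GAM is selected
only when its AIC is ≥ 2 units below the linear candidate's (ties and
near-ties go to the line, by parsimony), and the broken-stick model is
fitted only when the nonlinear model is selected.

**Broken stick.** Y = β0 + β1 X + β2 (X − c)₊ + ε, one breakpoint.
Estimation is Muggeo-style iterative linearization: at a working c the
model is linear in (1, X, (X − c)₊, −1[X > c]) and the indicator
coefficient updates c by γ/β2; iteration starts at the sample median,
tol 1e-8 on c, max 50 iterations. A 500-point grid search over interior
candidate breakpoints is the shipped oracle and the fallback when
iteration leaves the range or cycles. The breakpoint SE is the
delta-method se(γ)/|β2| from the final linearization. Two degeneracy
guards return the plain linear fit with c = None: (i) no interior
breakpoint improves the weighted SSE, and (ii) a Davies-type pretest for a
slope change at an unknown breakpoint (sup-|t| over a 20-point grid with
the total-variation tail correction) is non-significant at α = 0.05. The
pretest mirrors standard segmented-regression practice — the breakpoint is
a nuisance parameter absent under the null, so an unguarded sup-search
finds spurious breaks at well above the nominal rate.

Predictors (amount g/kg, size μm, time days) are fitted on the raw scale
by default, since the thresholds of interest are reported on raw scales; a
log-x transform is available for exploration. Zero crossings of a fitted
mean response are located by a 2001-point scan plus Brent refinement.

## Moderator importance

Moderators enter in both continuous and categorical form (one-hot encoded
levels named `moderator=level`); rows missing a modeled predictor are
dropped per-model with logged counts. Three rankings:

- random-forest permutation importance, expressed as % increase in MSE
  relative to the unpermuted fit; library defaults are 1000 trees and
  mtry = ⌈p/3⌉ (the pipeline uses 200 trees for speed);
- gradient-boosted trees (1000 trees, learning rate 0.01, depth 3 by
  default), relative influence normalized to sum to 100;
- a weighted variant that draws bootstrap samples with probability
  proportional to meta-analytic weights before each forest refit and
  averages importances across replicates.

Permutation p-values refit the forest on response-permuted data (default
99 permutations) and use the same permutation-importance settings for the
observed and null statistics, so under exchangeability the p-value is
uniform; with several predictors, predictor-level rejections at α are
therefore expected at roughly the nominal rate, and tests assert that
calibration rather than "no rejection anywhere". Absolute importances are
hyperparameter- and implementation-dependent; only rank order is treated
as meaningful, and all recovery tests are rank-based.

## Publication bias

Egger's regression (standardized effect on precision, OLS, t-test on the
intercept with k − 2 df) screens small-study asymmetry; a funnel exactly
symmetric about its mean yields a zero intercept identically. Rosenthal's
fail-safe N uses the z-sum method with the one-sided critical value
z_{1−α} (1.645 at α = 0.05, Rosenthal's convention), returning 0 when the
combined z-test is already non-significant; a brute-force oracle (adding
zero-effect studies one at a time) validates the closed form in tests.
Trim-and-fill and selection models are out of scope.

## Synthetic generator

`generate_meta_dataset` emulates the observation table of this literature:
48 studies × 15 comparisons (≈ 720 observations), parameter mix spanning
α-diversity metrics, biomass, six functionality indicators, and soil
properties; replicate counts uniform on 3–6; control means lognormal
(median 10, log-SD 0.5); group SDs = CV × mean with CV 0.15 (typical of
enzyme/biomass assays); amounts lognormal (median 5 g/kg, clipped to
0.1–100), sizes log-uniform 0.1–30 000 μm, times uniform 1–365 d;
moderator-dependent true effects additive on the lnRR scale with
independent N(0, τ² = 0.04) heterogeneity per observation; a configurable
fraction (default 0.2) of group SDs blanked for the imputation path. The
planted amount–functionality response is hormetic: slope +0.004 per g/kg
up to c = 40 g/kg, then −0.001 (positive but declining plateau). Observed
group means add sampling noise SD/√n around the truth.

What it does **not** emulate: correlation among moderators, within-study
clustering of effects, skewed or heavy-tailed measurement error, or
reporting/selection bias. Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to those
real-data features.

**Breakpoint recovery design.** Locating a slope change of 0.005 per g/kg
within ±10% at n = 400 requires residual SD ≈ 0.03–0.04 on the lnRR scale
(threshold precision scales as σ/|β2|). The dedicated
`dose_recovery_design` therefore uses 400 functionality observations,
amounts lognormal around 20 g/kg (mass on both sides of the break), 8–12
replicates, CV 0.05, and τ² = 5e-4. This is an identifiability design for
testing the estimator; the default generator keeps the noisier,
field-realistic regime (where a threshold this shallow is genuinely not
recoverable — itself an informative fact for study planning).

## Numerical choices and edge cases

- REML search interval: [0, max(10·var(e), 10·max v)]; the boundary
  candidate τ² = 0 is compared explicitly against the interior optimum.
- Zero sampling variances are floored at 1e-12 in weighting contexts.
- Constant responses: GAM returns a flat fit; importance raises (MSE
  undefined); linear fit on constant x raises rank-deficiency.
- Grid searches skip candidate breakpoints leaving fewer than two distinct
  x values on either side.
- Ties in model selection go to the linear model.
- Every stochastic routine takes an explicit seed; the pipeline derives
  all stage seeds from one config seed, and same-seed runs are
  byte-identical on the same platform.

## Problem sizes in tests and the acceptance script

Calibration tests use 300–1000 replicates for coverage/type-I rates,
100 seeds for breakpoint recovery, 200 simulations for model-selection
accuracy, and 20 seeds for importance rankings; the acceptance script runs
scaled versions (500/400/200 replicates, 20 recovery seeds, 5 importance
seeds) chosen to keep a full run around a minute while leaving Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

- Single breakpoint only; no multi-break or variance-changepoint models.
- No study-level random intercepts or robust (cluster) variance.
- GAM basis is fixed-knot B-splines with one smoothing parameter; no
  adaptive smoothing.
- The Davies correction is an upper bound, so the breakpoint pretest is
  mildly conservative.
- Importance p-values are exchangeability-based and inherit the forest's
  biases (e.g., split-variable preference for high-cardinality encodings).
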