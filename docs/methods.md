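# Methods

## Scope

`hrcentiles` implements a complete reference-curve and prediction-equation
analysis for heart-rate measures in an adolescent athlete cohort: synthetic
cohort generation, anthropometric derivations, LMS (Box-Cox Cole-Green)
centile estimation, age-decline summaries, stepwise regression, and
Bland–Altman agreement analysis.

## The Box-Cox Cole-Green distribution and the LMS method

A positive measurement x at age t is modelled so that its Box-Cox transform
is standard normal:

    z = ((x/M)^L − 1)/(L·S)   (L ≠ 0),    z = ln(x/M)/S   (L = 0),

with M(t) > 0 the median, S(t) > 0 the coefficient of variation and L(t) the
skewness power. The centile at cumulative fraction α is the inverse map
C_100α = M(1 + L·S·z_α)^(1/L). For |L| < 1e-7 the implementation switches to
the exact log-normal limit M·exp(S·z_α), which keeps percentiles and
z-scores continuous in L (verified to 1e-6 relative in the tests). For L ≠ 0
the transform requires 1 + L·S·z > 0; an infeasible tail raises an error
naming the (age, α) cell rather than returning a complex or clipped value.

### Fitting

Fitting is **two-stage**, so each stage has an independent oracle:

1. *Per-age-group maximum likelihood.* The log-likelihood per observation is
   L·ln(x/M) − ln S − z²/2 (additive constants dropped). It is maximised
   over (L, ln M, ln S) by Nelder-Mead from the moment start (1, ln median,
   ln(SD/median)), with convergence tolerances 1e-8 (parameters) and 1e-10
   (likelihood). The log parameterisation enforces M, S > 0 without
   constraints. A group needs ≥ 20 positive values with nonzero spread.
   The test suite checks the fitted likelihood against a brute-force grid
   around the optimum: the optimiser must never lose to the grid.
2. *Across-age smoothing.* Each of the L, M and S sequences is smoothed by a
   natural cubic smoothing spline in the Reinsch form, fitted values
   (I + λK)⁻¹y, with λ solved (Brent) so that the smoother trace equals a
   requested equivalent degrees of freedom. Defaults: edf 3 for L, 5 for M,
   3 for S, chosen so the median can track a curved age trend while the
   weakly identified L and S are strongly stabilised; edf = n disables
   smoothing and edf = 2 degenerates to the least-squares line. M is
   smoothed on the log scale so the result stays positive.

Identifiability: the curvature of the likelihood in L scales with S, so for
tightly distributed measures (S ≈ 0.03, typical of maximum heart rate) the
per-group L estimate is unbiased but noisy (SD ≈ 0.8/(S·√n)). This is the
standard motivation for smoothing L strongly across age and for reporting
centiles, which depend on L only through small skewness corrections.

### Reporting

The default centile set is {3, 10, 25, 50, 75, 90, 97}; the P50 column
reproduces the M sequence exactly, and columns are strictly increasing in α.
Decline summaries of a per-age series v₁…v_k report the mean and SD (n−1) of
the yearly declines vᵢ − vᵢ₊₁ and the overall percent change
100·(v_k − v₁)/v₁. Values are rounded (half away from zero, 2 dp) only at
the report layer; every table cell keeps full precision in the bundle.

## Synthetic cohort generator

The generator's defaults encode the cohort the analysis targets: n = 801
males, integer ages 11–18 drawn categorically with proportions
(12.23, 10.61, 13.61, 13.48, 13.11, 12.86, 10.99, 13.11) %. Ages are integer
years because the reference analysis groups by whole years.

* **MHR (linear mode, default):** 225.08 − 1.55·age + ε, ε ~ N(0, 5.22²)
  bpm. An optional BMI term (`mhr_bmi_slope`, default 0) produces the
  two-predictor structure used to exercise stepwise selection.
* **RHR:** linear interpolation of the endpoint medians (73.86 bpm at 11,
  63.64 bpm at 18) plus N(0, 5.8²) noise. The 5.8 bpm residual SD is
  back-derived from the age-11 P3–P97 reference spread
  ((84.52 − 62.59)/(2·1.8808)); rows violating 0 < RHR < MHR are redrawn
  (vanishingly rare at these parameters, but the invariant is enforced).
* **BCCG mode:** when per-measure (age, L, M, S) anchors are configured,
  each age group is drawn from the Box-Cox Cole-Green law with parameters
  linearly interpolated between anchors; draws with 1 + L·S·z ≤ 0 are
  rejected and redrawn. This mode anchors the LMS recovery tests at the
  published endpoint medians.
* **Anthropometrics:** age-linear Gaussian means chosen as realistic
  adolescent-male soccer values (height 1.45 m + 0.046 m/yr, SD 0.07 m;
  mass 38 kg + 4.5 kg/yr, SD 6 kg; four skinfold sites 5.5–9 mm with small
  age slopes, SD 1.5–2.5 mm), floored to stay positive. They feed only the
  BMI and body-fat operators and the stepwise candidate pool.

Randomness: one master seed; each stage (ages, anthropometrics, MHR, RHR)
derives its own generator from SeedSequence(seed, crc32(label)), so adding a
stage never perturbs another stage's draws and equal seeds give bit-identical
cohorts.

What the generator does **not** emulate: within-year age structure,
measurement error and digit preference of field heart-rate monitors,
correlation between anthropometrics and heart rates beyond an explicitly
configured BMI effect, non-Gaussian residuals in linear mode, and any
team/cluster structure. Passing tests therefore demonstrate that the
estimators recover known generating parameters under the stated sampling
design — not that any real population follows these curves.

## Anthropometric operators

BMI = mass/height². Body density from the four-skinfold sum s (triceps +
biceps + subscapular + suprailiac, mm) and age:
D = 1.0994921 − 0.0009929·s + 0.0000023·s² − 0.0001392·age (g/cm³), strictly
decreasing in s over the physiologic range (the quadratic's vertex is near
s = 216 mm). Body fat uses the Siri relation, reported on the percent scale:
BF% = 100·(4.95/D − 4.50). Exactly four sites are required; a missing site
is an error, never an imputation.

## Regression and agreement

* `fit_ols` (statsmodels behind the interface) reports coefficients,
  R² = 1 − SSE/SST, the standard error of the estimate
  SEE = √(SSE/(n − p − 1)) with p predictors, and the in-sample residual
  range.
* `stepwise_select` performs forward entry / backward removal on partial-F
  p-values with classical defaults p_enter = 0.05 ≤ p_remove = 0.10, and
  returns the model sequence plus a trace; an empty selection is a result,
  not an error.
* `bland_altman` uses differences **measured − predicted** throughout: an
  equation that predicts too low yields a positive bias. The 95 % limits are
  bias ± 1.96·SD with the sample (n−1) SD — the combination that reproduces
  published limit arithmetic exactly (e.g. 0.003 + 1.96·5.22 = 10.23).
* `group_compare` runs one-way ANOVA plus two-sample t tests for successive
  age pairs, Bonferroni-adjusted by the family size of 7 successive
  comparisons and capped at 1.

## Problem sizes and numerical choices

The stochastic recovery checks use 20 replicate cohorts of n = 801 for the
regression quantities and 10 replicates of 100 players per age (8 ages) for
the LMS median — sizes at which every reported tolerance comfortably exceeds
the Monte-Carlo standard error while the whole suite runs in seconds.
Degenerate inputs (constant groups, singular designs, infeasible tails,
non-positive measurements) raise typed errors naming the offending quantity;
ties in stepwise entry resolve to the smallest p-value by column order.

## Limitations

* The two-stage LMS fit is not the joint penalised-likelihood estimator;
  with small per-age groups the per-group ML step can be noisy in L, and the
  spline smoothing of noisy stage-1 estimates is not equivalent to smoothing
  inside the likelihood. Joint fitting with automatic roughness selection is
  deliberately out of scope.
* Reference curves are cross-sectional, male, single-sport and span integer
  ages 11–18 only; no longitudinal or sex-stratified modelling.
* The stepwise procedure inherits the usual caveats of data-driven selection
  (optimistic R², unadjusted post-selection inference).
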