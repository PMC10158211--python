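# Methods

`qbalin` performs deterministic quantitative bias analysis (QBA) for the
exposure coefficient of a linear regression when a confounder may be
unmeasured.  The observed data are a continuous outcome `Y`, a binary
exposure `X` and measured covariates `C`; the quantity of interest is the
coefficient of `X` in the regression of `Y` on `(X, C, U)` that *would* have
been fitted had the unmeasured confounder `U` been observed.  Because the
strength of `U` cannot be estimated from the observed data, each method takes
prespecified bias (sensitivity) parameters `phi` describing `U`'s
associations with exposure and outcome, and reports how the naive estimate
`beta_hat_{X|C}` would change.  Deterministic means each `phi` value gives
one adjusted result; no prior distribution is placed over `phi`.

## The naive fit and summary-only mode

All methods condition on the same `NaiveFit`: the OLS estimate, its SE,
t-value and residual degrees of freedom `df = n - (covariates + 2)`
(intercept and exposure counted).  Partial R^2 values are computed from
t-statistics as `t^2/(t^2 + df)` and partial correlations as
`t/sqrt(t^2 + df)`; both agree with explicit residual-on-residual regression
to 1e-10 (property-tested).

`summary_from_published` reconstructs the fit from printed numbers: given a
point estimate, its two-sided CI, `n` and the covariate count, the SE is
`(ci_high - ci_low) / (2 t_{(1+level)/2, df})` using the Student-t quantile
(not the normal), so downstream df-dependent statistics are consistent.
Methods that need only this summary (partial-R^2, E-value, threshold) run
without unit-record data; benchmarking and the outcome-modifying methods
require the data and refuse summary-only input with an explicit message.

## Partial-R^2 adjustment and robustness values

Bias parameters: `r2_xu = R^2_{X~U|C}` and `r2_yu = R^2_{Y~U|X,C}`.  The
adjustment

    bias  = se * sqrt(df) * sqrt(r2_yu * r2_xu / (1 - r2_xu))
    se'   = se * sqrt((1 - r2_yu)/(1 - r2_xu)) * sqrt(df/(df - 1))

is an exact sample identity: for a real omitted regressor, plugging in the
regressor's sample partial R^2 values reproduces the coefficient and SE of
the regression that includes it, to machine precision.  The test suite
asserts this at 1e-8 over replicated synthetic cohorts — it is the module's
primary oracle, independent of the formulas themselves.

The robustness value RV(q) is the minimal equal strength
`r2_xu = r2_yu` that removes a fraction `q` of the estimate; with a
significance level it instead drives the adjusted t (at `df - 1`) to the
critical value.  With `f = |t|/sqrt(df)` and `f_q = q f` (or
`q f - t*_{df-1}/sqrt(df-1)`),

    RV = ( sqrt(f_q^4 + 4 f_q^2) - f_q^2 ) / 2,

returning 0 when the significance criterion is already met.  The worst-case
bound (U explaining all residual outcome variance) is
`r2_xu = f_q^2/(1 + f_q^2)`; a brentq root-finding oracle confirms it.

## E-values

For a risk ratio `RR`, the E-value `RR' + sqrt(RR'(RR'-1))` (with
`RR' = max(RR, 1/RR)`) is the minimal equal pair of risk-ratio associations
`(RR_XU, RR_UY)` whose bounding factor
`B = RR_XU RR_UY / (RR_XU + RR_UY - 1)` reaches the observed ratio.  Linear
effects are first standardized, `d = estimate/SD(Y)`, then converted with
`RR ~ exp(0.91 d)` — the conventional constant (sqrt(3)/pi on the log scale)
for mapping a mean difference to a risk ratio.  The CI on the d scale uses
the normal quantile; at several hundred df the difference from the Student t
is below 0.01 on the E-value scale.  Benchmark E-values refit the naive
model leaving one covariate out and take the E-value of the leave-one-out
versus full effect ratio on the RR scale.

For round-trip testing against data generated with a known binary confounder
the package also exposes the prevalence-informed bias factor
`(1 + (RR_UY - 1) p1) / (1 + (RR_UY - 1) p0)` with `p1, p0` the confounder
prevalences in the exposed and unexposed groups; unlike the worst-case
bounding factor, this recovers the actual bias to first order and makes the
E-value route comparable with the exact-adjustment routes.

## Percent bias and the impact threshold

Percent bias asks what share of the naive estimate confounding must account
for before the p-value crosses `alpha`: `100 (1 - t* se/|estimate|)` when
the estimate is significant ("invalidate"), and the mirrored growth
percentage otherwise ("sustain").  The impact threshold (ITCV) works on the
partial-correlation scale: with `r = t/sqrt(t^2 + df)` and `r#` the
correlation matching the critical t, `ITCV = (|r| - r#)/(1 - r#)` is the
product `r_xu r_yu` at which the estimate sits exactly on the significance
boundary, and `sqrt(ITCV)` is the equal-correlation threshold.  Both use the
naive df for the critical value (no `df - 1` correction), which is the
convention that reproduces the worked values for the motivating example.
The exact partial-correlation recursion
`r' = (r - r_xu r_yu)/sqrt((1-r_xu^2)(1-r_yu^2))`, with the residual-SD
rescaling, yields an adjusted estimate that is again exact for a real
omitted regressor; the suite verifies it against direct regression and uses
a constructed confounder with exact sample correlations to confirm the
threshold's boundary behaviour on both sides.

## Confounding-function adjustment

The confounding function `q(x; alpha)` is the assumed difference in the
potential outcome `Y(x)` between exposed and unexposed at the same
covariates.  The built-in one-sided function takes this difference to be a
constant `alpha` in both arms; expressed from each observed row's
perspective it is `+alpha` for the exposed and `-alpha` for the unexposed,
and the de-biased outcome is

    Y_adj_i = Y_i - q(X_i; alpha) (1 - Pr(X = X_i | C_i)),

with propensities from a logistic regression (probit available by a switch),
clipped to [1e-6, 1-1e-6] with the clip count logged.  Regressing `Y_adj` on
`(X, C)` gives the adjusted effect.  The adjustment is linear in `alpha`, so
the whole sensitivity curve is a line and the null tipping point is
`alpha_0 = naive/slope` in closed form (verified against bisection).

`alpha` may be given as a signed variance share `r2_alpha` through
`alpha = sign * sqrt(|r2_alpha| * sigma2_naive)` — `|r2_alpha|` is the share
of unexplained outcome variance attributed to confounding and the sign its
direction.  This mapping is isolated in one function
(`ConfoundingFunctionParams`) and covered by an inversion test, since
variance-share conventions differ between implementations.  Curve benchmarks
use each covariate's partial R^2 with the outcome given `(X, C_-j)`; the
conditioning set is a documented choice.

## Latent-confounder simulation

For fixed `(zeta_y, zeta_x)` — `U`'s coefficients in the outcome model and
the probit treatment model — a stochastic-EM sampler alternates between
fitting the two models with the `U` terms held as offsets and redrawing each
`U_i` from its exact conditional distribution given `(Y_i, X_i, C_i)`.
Binary `U` uses direct two-point enumeration of the conditional weights
(validated against a brute-force enumeration oracle on a toy dataset);
standard-normal `U` uses truncated-normal augmentation of the probit so the
Gibbs update stays exact.  Exposure-coefficient draws after burn-in are
pooled across independent chains with the multiple-imputation rule
`total variance = within + (1 + 1/m) between` (a "mean of SEs" alternative
is available).  Defaults: 60 iterations, 10 burn-in, 20 chains — desk-scale
settings with precision knobs; the tests and the acceptance run use smaller
chains/iteration counts, which the recovery checks show are sufficient at
n ~ 550.

Because the `zeta` coefficients are offsets rather than free parameters,
`zeta_y = 0` makes every kept draw equal the naive estimate identically (the
conservation law, asserted draw-by-draw).  Continuous-`U` runs agree with
the closed-form partial-R^2 adjustment at the sample partial R^2 of the
realized confounder, which ties the stochastic and analytic routes together.
Standardization (`standardize_for_sensitivity`) centres and scales the
outcome and continuous covariates so that `zeta` benchmarks are comparable
across variables; binary columns are untouched, and a scaling record
back-transforms results to outcome units.

## Benchmarking and the comparative report

Benchmarks translate measured covariates onto each method's parameter scale
(partial R^2 pair, partial-correlation pair, leave-one-out E-value, outcome
partial R^2, standardized coefficient pair).  They are labelled *informal*:
they summarise the data-fitted strengths of measured covariates and do not
adjust for the omission of `U` itself, so they understate what a confounder
correlated with `C` could do.  The strongest covariate is the one with the
maximal product of its two strengths on the method's own scale (ties broken
by column order with a warning).

The comparative report evaluates each selected method at multiples
{0.5, 1, 2} of the strongest covariate's benchmark in both bias directions,
alongside the naive row (and a fully adjusted row when the analyst can pass
a realized confounder, as in simulation studies).  Threshold-style methods
contribute significance verdicts rather than adjusted estimates.  Method
failures are captured per cell.

Tipping points are solved along each method's equal-parameter diagonal:
closed-form paths by brentq bisection to 1e-8 relative tolerance, stochastic
paths by grid bracketing with refinement and Monte-Carlo error bars.  Every
solved point re-evaluates its criterion at the locus (1e-6 for closed-form
methods, 3 MC-SE for stochastic ones) and records the residual.

## Synthetic cohorts

The generator emulates a birth-cohort follow-up: correlated baseline
covariates (exchangeable latent correlation, optional binary thresholding),
a binary exposure from a probit model, a continuous outcome, and one
withheld confounder, binary or standard normal, independent of `C`.
Presets:

* `bcg_like` — n = 542, true effect 2.19, seven covariates with a
  maternal-weight analogue strongest on both exposure and outcome, binary
  confounder with outcome coefficient −0.66 and probit exposure coefficient
  −0.14 (the logistic value −0.23 divided by 1.6), exposure prevalence 0.25,
  residual SD tuned so the naive SE matches 0.4606;
* `null_confounding` — the same cohort with the confounder switched off;
* `strong_confounder` — n = 542, effect 2.0, three covariates, binary
  confounder with `zeta_y = 2.0`, `zeta_x = 0.8`, residual SD 4.0.

Residual-SD tuning exploits that the squared naive SE is affine in the
residual variance (`se^2 = A sigma^2 + B`, the withheld confounder
contributing to `B`): two pilot batches identify `(A, B)` and the target SE
solves in closed form.  `implied_phi` converts the generating confounder to
each method's parameter scale from one large Monte-Carlo cohort — sample
partial R^2 and partial correlations for the analytic methods, the
C-partialled prevalence contrast and `exp(0.91 zeta_y / SD(Y))` for the
risk-ratio scale, and the constant confounding amount
`zeta_y * (partial prevalence difference)` for the confounding function.
The toolkit's central correctness property is the round trip: every method
evaluated at its implied parameters returns, in replicate mean, to the
generating effect.

What the generator does *not* emulate: confounders correlated with measured
covariates, non-normal outcome errors, measurement error, longitudinal
structure, or survey weights.  Passing tests therefore demonstrate internal
consistency of the methods under a correctly specified generating model, not
robustness to those real-data features.

## Numerical choices and limitations

* Probit fits start from the zero vector (Newton/Fisher scoring) so repeated
  fits are bit-identical; the sampler's inner solver adds a tiny ridge and
  step damping for extreme offsets, and agrees with the statsmodels-backed
  fit to 1e-6.  Perfect separation raises with a diagnostic.
* All randomness flows through `numpy.random.Generator` seeded from explicit
  seeds; per-chain and per-grid-node seeds derive from `SeedSequence` spawns,
  so every simulation result is reproducible bit-for-bit.
* Contour level sets are extracted by marching squares on the analytic
  surface (default 201x201 grid on [0, 0.4]^2); the naive level set of the
  partial-R^2 surface is the two axes and is emitted analytically.
* Benchmark proportions are capped at 1 - 1e-6; propensities clipped at
  1e-6.  Degenerate inputs (zero residual variance, constant covariates,
  rank-deficient designs) are flagged or rejected with named columns.
* Group benchmarks (bounds from several covariates jointly) are not
  implemented; negative-estimate problems are handled by sign symmetry.
* The sampler fixes `(zeta_y, zeta_x)` rather than estimating them; its
  equivalence to other samplers for the same model is claimed only up to the
  invariants above (conservation, recovery, continuous-U agreement).
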