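# Methods

`deplife` builds sex-, age- and deprivation-specific period life tables from
abridged small-area mortality counts: one row per (census tract, sex,
calendar year, 5-year age band) with a death count and person-years, plus an
area-level deprivation quintile (Q1 least deprived … Q5 most deprived).
This note records the model, the choices that were genuinely open, and what
the synthetic validation does and does not demonstrate.

## The smoothing model

Death counts are Poisson with a log link and log person-years offset:

    log E[deaths_ij] = log(PY_ij) + b0 + f1(age_i) + sum_{q=2..5} b_q 1{Q_i=q}
                       + f2(Q_i x age_i) + u_j,
    u_j ~ Normal(0, sigma_u^2)

* `f1` is a restricted cubic spline in the band's representative age —
  Harrell parameterization: a linear column in (age − 60) and truncated-cubic
  columns normalized by (t_k − t_1)², linear beyond the boundary knots.
  Default knots {2, 12, 22, 32, 42, 52, 67, 82} years; `select_knots`
  re-derives them on new data by 5-fold cross-validated mean absolute error
  between observed and predicted rates, folds stratified by quintile and
  age band, ties broken toward fewer knots then smaller ages.
* `f2` is the full elementwise product of the spline columns with the
  quintile indicators (Q1 is the reference), so every quintile has its own
  smooth age profile. With k knots the fixed part has 1 + (k−1) + 4 +
  4(k−1) columns (40 for the default 8 knots).
* `u_j` is a non-spatial census-tract random intercept (lognormal frailty on
  the rate scale). No spatial structure and no calendar-year smoothing:
  years enter only as pooled observation rows, and models are always
  fitted per sex.
* Representative age: band midpoint (lower + 2.5); the open 85+ band is
  assigned 90 years, approximating the deaths-weighted mean age in that
  band. Configurable (`open_band_age`).

### Fitting

The Laplace-approximated marginal likelihood is maximized with a penalized
IRLS inner loop that solves jointly for (beta, u) at fixed sigma_u — the
area block of the normal equations is diagonal, so u is absorbed by a Schur
complement and each iteration costs O(n p² + J) — and a bounded
one-dimensional search (Brent, on [1e-6, 2]) over sigma_u.  The Laplace
objective at the joint mode is

    l(sigma) = l_Poisson(beta, u) − sum_j u_j²/(2 sigma²)
               − ½ sum_j log(1 + sigma² sum_{i in j} mu_i).

Convergence: penalized log-likelihood change < 1e-8 (inner), maximum 200
iterations per inner solve, step halving on any decrease.  Non-convergence
raises; it is never silent.  `sigma_u=0` reduces the fit exactly to a plain
Poisson GLM, which the tests verify against statsmodels' independent IRLS
to 1e-6.  A one-off cross-check against R `glmmTMB` (an independent Laplace
implementation) on a frozen synthetic dataset agrees to ~2e-3 on
coefficients and ~7e-5 on sigma_u; the small residual is expected because
glmmTMB also profiles the Laplace determinant term when updating beta,
whereas the inner loop here maximizes the joint penalized likelihood.

`vcov(beta)` is the fixed-effect block of the inverse penalized Fisher
information (random effects profiled out, sigma_u treated as fixed), and
predicted rates carry delta-method intervals on the log scale:
exp(x'beta ± 1.96 sqrt(x' V x)).  Quintile-level predictions set the random
intercept to 0 (the median tract); `mode="mean"` instead multiplies by
exp(sigma_u²/2), the frailty-law average — the median convention is the
default because life tables describe a typical area, not the
frailty-skewed mean.  Tract-level predictions use the tract's
empirical-Bayes intercept.

Knot cross-validation fits the fixed-effects model only (no random
intercept) by default: held-out prediction uses the fixed part alone and
knot placement concerns the fixed age smooth; `random_intercept=True`
restores the full fit at ~10x the cost.

Crude rates are displayed per 1,000 person-years by default
(`display_scale`); published national tables sometimes label such columns
"per 100,000" while printing per-1,000 figures, so the scale is explicit
in the configuration rather than inferred.

## Life tables

Complete (single-year) tables are built from predicted rates at ages
0…99 plus an open interval at 100+ (beyond the last knot the spline's
linear tail is extrapolated).  Separation factors: a(0) = 0.1 (low-mortality
infant convention), a = 0.5 at other closed ages, q = m/(1 + (1−a)m) capped
at 1, open interval q = 1 and L = l/m, radix 100,000.  An abridged
constructor (5-year bands, a = n/2) is provided for band-level rates; with
central (survival-weighted) band rates it reproduces the continuous oracle
within 0.05 years for the default hazards.  Single-year construction from
the smooth model is the default because the spline is continuous in age and
the a-convention sensitivity of 5-year intervals is avoided.

Province LE is the person-years-weighted mean of tract LE over the whole
study period (not a life table from pooled province rates, which differs
slightly; the pooled alternative can be assembled from `stratum_rates` +
`abridged_rates_to_lifetable`).  LE quintile maps are rank-based with ties
broken by unit id, bin sizes differing by at most 1.

## The synthetic generator and what passing tests show

The generator emulates the structure of the Spanish 2011 census-tract
mortality cession without reproducing its geography: ~20% of areas per
quintile (rank-based on a simulated deprivation score), mean tract
population 1,311 (lognormal, log-sd 0.3 — the inter-tract dispersion is not
published, so this is a package choice), a fixed southern-European age
template over bands 0–4 … 85+, years 2011–2013.

The true hazard is Gompertz–Makeham, mu0(a) = c + b e^{theta a}, with a
multiplicative quintile effect linear in age on the log scale and a
lognormal tract frailty.  Default baselines (c = 2.0e-4, b = 2.35e-5,
theta = 0.0975 for men; 1.0e-4, 6.66e-6, 0.1075 for women) were calibrated
once against the package's own fine-grid survival integrator so that LE at
birth sits at realistic Spanish levels (middle quintile 77.3 / 82.9 years)
with a built-in Q1–Q5 gap of 3.5 years; `with_quintile_gap` re-solves the
Q5 effect for any requested gap, interpolating intermediate quintiles
linearly in rank.  The default age slope is −effect/90, closing the
proportional deprivation gap at age 90, which mirrors the observed pattern:
absolute rate differences negligible below 15 (rates are tiny),
proportional differences closing at the oldest ages, the bulk of the gap at
working ages.  A linear-in-age log-gap cannot also *rise* from zero at
young ages, so the generator slightly overstates proportional (not
absolute) young-age differences; tests therefore compare the young-age
spread on the rate scale and the old-age spread on the log scale.

Band-level expected deaths use survival-weighted band-average hazards
(the band's central death rate, exactly what abridged count data measure)
for all bands, including the open one (integrated to 120 years).

The oracle `true_life_expectancy` integrates survival by the trapezoid rule
(step 0.01 y, upper bound 120 y) on the closed-form cumulative hazard, with
the analytic tail S(T)/mu(T); halving the step moves results by < 1e-4 y.

What this validates — and does not: parameter recovery shows the estimator
chain (design → Laplace fit → delta intervals → life table → aggregation)
is consistent and approximately unbiased *when the data follow the model's
own error structure* (Poisson counts, lognormal frailty, proportional
quintile effects).  Real census-tract data add migration, late
registration, tract-boundary churn and non-proportional deprivation
effects that the generator does not emulate.

## Problem sizes used in the validation suite

Chosen once, from pilot variance calculations, and fixed:

* Gap recovery: 1,500 tracts x 3 years x 20 seeds per built-in gap
  (2, 3.5, 5 y), both sexes.  At 500 tracts the Monte-Carlo SD of the
  estimated gap is ~0.5 y, so mean absolute error would be noise-floored
  near 0.4 y regardless of estimator quality; 1,500 tracts brings the SD
  to ~0.29 y and makes the 0.3 y error budget a test of bias, not noise.
* Frailty recovery: 500 tracts x 3 years, true sigma_u = 0.3, 20 seeds.
* Delta-interval coverage: 200 tracts, mean population 4,000, 3 years,
  males, 500 parametric-bootstrap replicates from a first fitted model
  (bootstrapping from the fit, not the generator, isolates interval
  calibration from spline approximation error).  Smaller fixtures
  quasi-separate — some quintile has no deaths across the young bands,
  the MLE escapes to the boundary and the delta method does not apply;
  the fitter warns when this happens.
* Knot cross-validation: 100 areas, mean population 50,000, 3 years
  (~5M person-years/year/sex, the national scale at which knot positions
  are actually chosen).  At census-tract exposure (~70 person-years per
  cell) per-row rate MAE is dominated by Poisson noise and cannot rank
  knot placements — a real limitation of rate-scale CV on sparse cells,
  documented rather than hidden.

## Known limitations

* One random intercept per tract; no spatial correlation, no tract-level
  covariates beyond the quintile.
* The Laplace approximation mildly underestimates sigma_u when tracts have
  very few deaths (here ~2% at 6 deaths/tract).
* Quasi-separation on small datasets (zero-death strata) yields unbounded
  quintile-specific tails; the fitter warns but does not penalize.  A ridge
  or Firth-type correction would be a natural extension.
* Predictions above age 99 extrapolate the spline's linear tail; the open
  interval at 100+ keeps the extrapolation's influence on LE small.
* Province LE of a one-tract province is that tract's empirical-Bayes LE,
  which is shrunken toward its quintile mean.
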