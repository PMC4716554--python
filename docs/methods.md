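# Methods

## Model

The package fits a negative binomial (NB2) regression of daily death counts
on a distributed-lag non-linear temperature term plus confounder controls:

    Y_t ~ NegBin2(mu_t, theta),  Var(Y_t) = mu_t + mu_t^2 / theta
    log mu_t = alpha + cb_t' beta_cb + DOW_t' beta_dow
               + NCS(t; df_time)' beta_time
               + NCS(RH_t; df_rh)' beta_rh + NCS(D_t; df_dp)' beta_dp

`cb_t` is the cross-basis row for day t: for an exposure basis N_1..N_J
(natural cubic splines in temperature) and a lag basis M_1..M_K (intercept
plus natural cubic splines in lag, evaluated at integer lags 0..L),
column (j,k) is `sum_l N_j(x_{t-l}) M_k(l)`. The coefficient surface
f(x,l) = sum_jk beta_jk N_j(x) M_k(l) is the log rate ratio contributed by
exposure x at lag l; every reported effect is a linear contrast of it.
Assumptions worth stating plainly: effects of temperature on mortality are
additive on the log scale across lags; the surface is smooth in both
dimensions with the smoothness fixed by the chosen dfs; seasonality and
trend are captured by a spline in the day index rather than by monthly
indicators; population at risk is treated as constant (no offset); and
counts are conditionally independent given the covariates (no epidemic
dynamics).

## Spline construction

Natural cubic splines are parameterized in *cardinal* form: with the full
knot sequence k_1 < ... < k_K (boundaries plus interiors), basis function j
is the unique natural cubic spline equal to 1 at k_{j+1} and 0 at the other
knots; the first knot's cardinal function is dropped to exclude the
intercept direction. This choice makes basis values reproducible from an
independent truncated-power construction (the equivalence is tested at
1e-8), makes coefficients readable as values-at-knots, and is exactly
translation-equivariant. All downstream quantities — fitted means, AIC,
relative risks — are invariant to the parameterization, and the tests
assert that invariance separately.

Default knot placement: equally spaced quantiles of the observed values for
the temperature, time and confounder dimensions (boundary knots at the
min/max); equally spaced values on [0, max_lag] for the lag dimension. The
lag dimension's quoted df counts an explicit intercept column (so a 1-df
lag basis is a pure moving-sum effect); `lag_intercept=False` switches to
the all-spline convention, and `lag_stratified=True` gives one indicator
per lag (the unconstrained distributed lag model). Evaluation beyond the
boundary knots continues linearly — the natural condition — so prediction
grids may slightly exceed the observed range. Rows whose lag window reaches
before the series start or spans a missing day are flagged incomplete and
excluded from fitting; they are never imputed or silently dropped, so row
alignment with the calendar is preserved.

## Estimation and inference

The NB2 likelihood is maximized jointly over coefficients and dispersion
(statsmodels), warm-started from a Poisson GLM with a moment estimate of
the overdispersion. When the overdispersion estimate collapses to zero the
fit degrades to the Poisson limit and `dispersion` is reported as infinity.
AIC is −2 loglik + 2(p + 1), always counting the dispersion parameter so
that comparisons across the selection grid are on one convention.

Relative risks: for a contrast (at vs ref) over lag window W the log-RR is
c'beta_cb with c built from basis differences; the 95% CI is Wald,
exp(c'beta ± z_{0.975} sqrt(c'Vc)). The delta-method interval is checked
against a 100,000-draw multivariate-normal parametric bootstrap (agreement
within 0.5%). Percentiles (1st/50th/99th by default) are empirical
quantiles with linear interpolation, computed from the temperature values
actually entering the fit. Cumulative-RR curves across the eight lag
windows 0–1 … 0–28 can either re-summarize the single max-lag-28 fit or
re-fit the model per window (`refit_per_window`, default on, shrinking the
lag df to the window length when needed); the percentile effects table
always comes from the single final fit, matching how such tables are
conventionally produced.

## Model selection

`select_model` decides four components — time df/year, temperature
indicator (maximum/average/minimum), temperature df, lag df — either
sequentially in that order (components not yet decided held at the
midpoints of their candidate lists) or by an exhaustive Cartesian grid.
Ties break toward fewer df, then toward average temperature. Every
attempted fit lands in the trace with its AIC or failure reason. The
`hue2016` preset ships the final all-cause configuration (average
temperature, 4x5 df, max lag 28, 5 df/year, 3+3 confounder df) for use
without selection. Default candidate ranges (time 3–10/year, dfs 2–6) are
package choices: they bracket the preset values and the ranges customary in
this literature, and are fully configurable.

## Synthetic data generator

The generator emulates the structure of a five-year tropical single-city
series. Daily average temperature = mean (25.7 °C) + annual cosine
(amplitude 4.6 °C, peak near day 190) + stationary AR(1) noise (phi = 0.7)
whose variance is derived so the marginal SD is exactly the configured
4.1 °C. Maximum/minimum temperatures add/subtract gamma-distributed offsets
(means 4.2/4.0 °C, matching the observed spreads of the three indicators);
dew point subtracts a seasonally modulated depression (mean 3.6 °C, smaller
in the Sep–Jan rainy season) and relative humidity follows from the
depression via the Magnus approximation, giving ~82% mean humidity. Counts
are NB2 (theta = 8, consistent with mean 3.4, SD 2.2) around a log rate
driven by a closed-form surface f(x,l), optional day-of-week effects
(+3% weekends) and trend. Stratified counts are multinomial/binomial
thinnings (cardiovascular 35.6%, cancer 17.3%, external 5.9%, male 53.5%,
age ≥65 65.5%), so strata partition the all-cause count by construction.

Surfaces: `null`, `linear`, `J` (heat only), `L` (cold only), `U` (both),
and `displacement` (acute heat excess on lags 0–2 with a compensating
negative lobe on lags 3–10, depth −0.6). Temperature responses are
quadratic ramps anchored so the cumulative log-RR at the hot/cold anchor
(32.4/15.8 °C vs 26.3 °C) equals the configured log(1.4)/log(1.8) —
magnitudes on the scale reported for this setting. The hot lag profile is
an exponential decay with a 4.5-day constant: concentrated at short lags
but smooth enough to lie essentially within the span of the preset's lag
spline (knots every 7 days). A sharper profile is *not* representable by
that spline and produces irreducible attenuation of the fitted lag-0
effect, which would make recovery experiments test misspecification rather
than estimation; the smoothness of the default is therefore part of the
experiment's design. The cold profile is a Gaussian bump (onset day 5,
width 7). `CrossBasisSurface` additionally builds truths lying exactly in
a chosen cross-basis span, used to study whether AIC selection recovers
the generating dimensionality.

What the simulator does not emulate: real weather dependence structure
beyond AR(1) (no weather regimes, typhoons, or multi-day heat-wave
persistence beyond autocorrelation), influenza or other seasonal mortality
drivers correlated with weather, reporting artifacts, or population change.
Passing recovery tests therefore demonstrates correctness of the estimation
machinery under the stated data-generating assumptions, not robustness of
the scientific conclusions to violations of them.

## Numerical choices and degenerate inputs

- Optimization: Newton first, falling back to BFGS/L-BFGS; non-convergence
  raises an error carrying the method trace. Rank-deficient designs warn.
- All-zero responses and non-integer or negative counts are errors; an
  all-constant count series fits cleanly in the Poisson limit.
- ICD-10 aggregation compares the leading letter+two-digit code against
  chapter ranges inclusively; unparseable codes count in all-cause only and
  are logged.
- Percentile rule package-wide: linear interpolation between order
  statistics.
- Simulation determinism: one integer seed drives every draw; identical
  seeds give bitwise-identical output.
- Dates are made contiguous on load; inserted gap days have missing weather
  and counts, which removes (flags) every lag window covering them.

## Problem sizes

Simulation-based checks use the study's native scale — five years
(1826 days, ~3.4 deaths/day) — with 50 replicates for coverage,
displacement-detection, error-control and selection-recovery experiments,
and 20–100 replicates for smaller calibration checks. These sizes give the
binomial margins quoted in the tests (e.g. a ≥90% coverage bound sits ~4 SE
below the ~95% observed rate) while keeping the full suite fast.

## Known limitations

- Wald CIs on the RR scale can undercover when counts are very sparse
  (strata with ≪1 death/day); the respiratory-scale stratum is near this
  regime.
- The type-I-control experiment runs inference from the preset model;
  when selection precedes inference on the same data the error rate is
  only approximately controlled.
- The sequential selection strategy is a greedy restriction of the
  exhaustive search and can settle in a different (never better) AIC
  optimum.
- No offset/population term and no air-pollution covariates; both are
  deliberate scope decisions mirroring the analysis the package implements.
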