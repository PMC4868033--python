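# Methods

This note records the statistical models implemented in `heatmort`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Exposure

The exposure indicator is the lag 0–3 mean of daily mean temperature: the
average of the current and three preceding days. Analyses are restricted
to the warm season, 1 May – 30 September (153 calendar days in every year),
the operating window of heat early-warning systems. Two boundary policies
govern the first days of each summer: `carry_in` (default) lets supplied
late-April days enter the rolling window before the output is restricted to
the warm season; `partial` restricts first and averages whatever lags are
available inside the season. Which the original analyses used is not
knowable from warm-season-only data; both are explicit options, and the
synthetic generator uses `partial` so that the generating model is exactly
the model fitted to warm-season-only records.

The apparent-temperature variant uses AT = −2.653 + 0.994·Tₐ + 0.0153·T_d²
(air temperature Tₐ, dew point T_d, °C), the definition standard in the
European heat-epidemiology literature; the coefficients are arguments, not
constants. `city_mean` aggregates per-grid-cell series to an unweighted
city mean, and `compare_series` reports the Pearson correlation and mean
bias of a modelled series against measurements.

## Segmented heat–mortality model

Daily death counts are Poisson with a log-linear predictor containing a
two-segment temperature term joined at the threshold T₀ plus confounders:
holiday dummy, six day-of-week dummies (Monday reference), four calendar
month dummies (May reference), linear and quadratic terms in a 0-based
year index (long-term trend), linear and quadratic dew point, and
optionally the lag 0–1 mean PM₁₀ concentration. Missing PM₁₀ is linearly
interpolated over gaps of at most 2 days; rows still incomplete are dropped
(complete case) with a logged count. Dropping the PM₁₀ term changes
columns only, never rows, when PM₁₀ is complete.

Estimation separates the threshold search from the final regression:

* **Threshold (maximum likelihood).** Default is Muggeo's iterative
  linearization on the Poisson likelihood: refit with the slope-difference
  term U = (T−T₀)₊ and gap term V = −I(T>T₀), update T₀ by γ̂/δ̂, starting
  from the exposure median, tolerance 10⁻⁴ °C, at most 50 iterations. The
  profile likelihood has kinks at the observed exposures, so the raw
  update can enter a two-cycle; the step is damped by a persistent factor
  halved on every direction reversal, and the converged value is polished
  by a local profile scan on a 0.01 °C grid so the reported threshold is
  the local ML point. The alternative `profile` estimator scans a 0.1 °C
  grid (configurable) between the 5th and 95th exposure percentiles and is
  an exhaustive search by construction; ties break toward the lower
  candidate. A threshold pinned at the search boundary is flagged.
* **Slopes and uncertainty (GEE).** At the selected T₀ the full model is
  fitted by generalized estimating equations with summers as independent
  clusters, a first-order autoregressive working correlation within each
  summer, and model-based ("naive") standard errors — the appropriate
  choice with few large clusters, where the robust sandwich estimator is
  unstable. The threshold standard error comes from the delta method on
  the naive covariance of (γ, δ) (Var(γ̂/δ̂)); for the profile estimator a
  local quadratic curvature of the profile likelihood is the fallback.
  Confidence intervals default to the 90 % level. Slopes are reported as
  percent change per °C, 100·(exp(β)−1); the accessor for the segment
  below the threshold reports percent change per °C of *cooling*
  (100·(exp(−β₁)−1)), matching the epidemiological reading of a reverse
  relation below the minimum-mortality point.

The exploratory curve is a natural cubic regression spline in the exposure
with df = 5 basis columns (mgcv-style centred `cr` basis, knots on the
exposure quantiles) added to the same confounder design and fitted by
Poisson GLM. The curve is centred at its minimum; pointwise Wald bands
(95 % by default) are computed from the spline-coefficient covariance and
shifted by the same centring constant (the centring constant's own
uncertainty is not propagated — the curve is a descriptive diagnostic).
Simulation checks show the bands hold their nominal pointwise coverage
under a flat truth; because pointwise failures are correlated along the
curve, joint statements ("flat over ≥90 % of the range") hold in roughly
80–87 % of replicates, not at the pointwise rate.

## Attributable deaths

AF_i = 1 − exp(−β₂ (T_i−T₀)) above the threshold and 0 at or below it.
Negative slope draws give negative AF; values are deliberately not
truncated, so the Monte Carlo distribution keeps its sampling shape. With
observed counts, AD = Σ Y_i AF_i. For projected years AD = P·r·γ·mean(AF)
with the crude mortality rate r (default 0.0093 = 0.93 %) and warm-season
death share γ (default 0.385; `estimate_gamma` computes it from complete
calendar years of daily counts). The product form is valid when the daily
correlation between counts and AF is small — i.e. heat is not the dominant
driver of daily mortality — and matches the exact daily-sum identity within
2 % in simulations satisfying that condition.

Monte Carlo propagation draws (β₂*, T₀*) independently from Normal
distributions centred at the point estimates with the fitted standard
errors (10,000 draws by default); γ and r are treated as known. A
joint-Normal option with the estimated (β₂, T₀) covariance is deliberately
not the default: the two draws are independent by design. Period summaries
average per-year AD over the period within each draw first, then summarise
across draws (mean, empirical 10th/90th percentiles with linear
interpolation); the alternative draws-then-years order is a config switch.
Years map to population projections year by year, not to a single
mid-period population. The same draw array is shared across all
scenario × population combinations so that "parameter draw" is a single
factor in the sensitivity decomposition.

## Population models

Exponential: P(t) = P_a (1+ρ)^(t−t_a) with ρ = (P_b/P_a)^(1/(t_b−t_a)) − 1.
Logistic: P(t) = K / (1 + A e^(−ρ(t−t_a))) with A = K/P_a − 1 and ρ solved
in closed form from the second anchor. Both are exact two-point
calibrations, evaluated in continuous time (fractional years allowed), and
reproduce both census anchors to machine precision; the logistic family
converges to the exponential one as K → ∞. Census anchors are
configuration inputs, not constants. Projection before the anchor year is
rejected — the models are calibrated forward from the census and are not
intended as back-casts — so baseline analysis periods must start at or
after the anchor year (or use a fixed population, which
`monte_carlo_impact` accepts directly).

## Variance-based sensitivity analysis

The total-effect index of factor Xᵢ on Y = AD per year is
S_T = E(Var(Y|X₋ᵢ))/Var(Y) = 1 − Var(E(Y|X₋ᵢ))/Var(Y). Because the
pipeline evaluates AD on a full-factorial grid (draw × year × climate
model × population model), both conditional moments are computed exactly by
grouping over complement-factor cells; no Saltelli-type design is needed.
Population (ddof = 0) variances make the two algebraic forms identical on
any finite grid. Indices include interaction contributions, so their sum
can exceed 1. For the baseline period a reduced draw × year grid is used
(a single calibrated climate model, and the absent factors are reported as
missing). Against analytic benchmarks the estimator reproduces Sobol
values for additive models and the pure-interaction case within 0.02 at
the default grid sizes.

## Synthetic data generator

The daily-series generator produces exactly the structure the estimator
assumes: Poisson counts with the two-segment exposure term evaluated at the
lag 0–3 exposure, configurable confounder contributions (keyed by the
design-matrix column names), and within-summer serial dependence through a
Gaussian AR(1) log-frailty added to the linear predictor (marginal sd 0.05
by default, autocorrelation 0.7); summers are independent. Temperatures
are a seasonal sinusoid over the 153-day window carrying 60 % of the
variance plus AR(1) Gaussian noise (lag-1 correlation 0.7); dew point is
temperature minus a lognormal offset; PM₁₀ is lognormal with correlation
0.2 to temperature so confounder adjustment is non-trivial. Default
generating truths are the study conditions: threshold 19.7 °C, slope above
ln(1.0170) (+1.70 %/°C), slope below −ln(1.0411), about 10 expected deaths
per day at the threshold, warm-season temperature mean 20.7 °C and sd
4.0 °C (so the 95th percentile sits near 27.4 °C), five summers. One
master seed spawns per-summer sub-streams (numpy `SeedSequence`), so
extending a series never reshuffles earlier summers.

Scenario ensembles use the same seasonal-plus-AR(1) construction with an
additional per-year Normal shift (inter-annual variability, default sd
0.8 °C), followed by one affine adjustment that matches the pooled
warm-season mean and 95th percentile to the configured targets exactly on
the generated sample.

What the generator does *not* emulate: the marginal distribution of real
daily temperatures (the sinusoid+AR(1) choice is a stand-in, not an
inference about any city's climate), mortality displacement, heat-wave
add-on effects, age structure, long-term demographic or adaptation trends,
and any physical urban-climate modelling. Passing tests therefore
establish the statistical correctness of the estimators under the assumed
generating structure — not the climatological realism of the inputs.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately compact sizes
chosen as sufficient for the statistical checks: 5-summer series (the
study's own sample-period length) for fitting, 200 replicates for the
parameter-recovery study, 20-year ensembles per scenario, 10,000 Monte
Carlo draws for impact propagation, and 2000-level factor grids for the
analytic Sobol benchmarks. Degenerate inputs are handled explicitly:
zero standard errors collapse the Monte Carlo to the point estimate
exactly; zero total variance makes total-effect indices undefined (error);
constant series make the Pearson correlation undefined (flagged, not
raised); thresholds pinned at the search boundary and non-converged fits
are flagged rather than silently accepted, and non-converged fits are
refused by the impact stage.

## Known limitations

* The threshold's delta-method standard error inherits the known slight
  undercoverage of Muggeo-type intervals (about 84 % observed at a nominal
  90 % in a 40-summer recovery study); slope intervals are well calibrated.
* The GEE working correlation assumes equally spaced days within a summer.
* The product approximation for projected AD assumes a constant r and γ
  over time, as the impact framework prescribes.
* Attributable deaths are not adjusted for mortality displacement and
  cold-related mortality is out of scope.
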