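# heatmort

Health impact assessment of heat-related mortality for a city under climate
change: estimate the temperature–mortality relationship from daily
warm-season time series, project heat-attributable deaths under future
temperature scenarios and population growth models, propagate parameter
uncertainty by Monte Carlo, and decompose the variance of the projections
into its sources. Built for epidemiologists and public-health analysts who
need the full chain — exposure–response estimation through scenario impact
tables — as a reproducible, testable Python library.

## Model

Daily all-cause death counts during the warm season (1 May – 30 September,
*n* = 153 days) are modelled as

```
y_i ~ Poisson(λ_i)
log(λ_i) = α + confounders + β₁ (T_i − T₀) I(T_i ≤ T₀) + β₂ (T_i − T₀) I(T_i > T₀)
```

where `T_i` is the lag 0–3 mean temperature (average of the current and
three preceding days), `T₀` the minimum-mortality threshold at which the
two linear segments join, and `β₁`, `β₂` the log-scale slopes below and
above it. Confounders are dummies for holidays, day of week and calendar
month, a quadratic long-term trend, a quadratic in dew point, and
optionally the lag 0–1 mean of PM₁₀. The threshold is a maximum-likelihood
estimate (Muggeo's iterative linearization, or an exhaustive profile-grid
search); slopes and standard errors come from a GEE fit with summers as
independent clusters, an AR(1) working correlation within summers, and
model-based (naive) standard errors. An exploratory cubic regression
spline (5 df, knots on exposure quantiles) visualises the curve before the
segmented fit is imposed.

Impacts follow the attributable-fraction identities

```
AF_i = 1 − exp(−β₂ (T_i − T₀) I(T_i > T₀))          (daily attributable fraction)
AD   = Σ_i Y_i AF_i                                  (observed counts)
AD   = P · r · γ · mean(AF_i)                        (projected periods)
```

with `P` the projected population (exponential or logistic growth
calibrated exactly through two census anchors), `r` the crude mortality
rate and `γ` the warm-season share of annual deaths. Sampling variability
of `(β₂, T₀)` is propagated by 10,000 independent Normal draws, and the
contribution of each uncertainty source (parameter draw, year, climate
model, population model) to `Var(AD/year)` is measured by total-effect
indices `S_T = E(Var(Y|X₋ᵢ)) / Var(Y)` computed exactly on the pipeline's
full-factorial output grid.

A synthetic-data module generates daily series with exactly this generating
structure (plus GCM-style warm-season temperature ensembles calibrated to
target mean / 95th-percentile pairs), so every stage is testable with known
truths and no external data.

## Worked example

`python examples/fit_heat_mortality.py` simulates five warm seasons with a
known two-segment effect and recovers it:

```
spline curve minimum (minimum-mortality exposure): 20.3 deg C
threshold T0: 20.5 deg C (90% CI 19.5; 21.5)
mortality change above T0: +3.13 % per deg C
mortality change below T0: +4.88 % per deg C of cooling
AR(1) working correlation: 0.077; converged: True
```

The generating truths were T₀ = 19.7 °C, +1.70 %/°C above and +4.11 %/°C of
cooling below; the estimates differ from them only by the sampling noise of
a 5-summer series (the threshold's 90 % CI covers the truth). The other
examples cover population projection (`population_projection.py`), Monte
Carlo impact projection (`project_attributable_deaths.py`, e.g. 364 deaths
per year, 10th–90th percentile 228–499, under an end-of-century ensemble)
and the variance decomposition (`variance_decomposition.py`). The
end-to-end pipeline — fit → project → impact → sensitivity, with CSV/JSON
reports — runs from a single config via `heatmort.run_pipeline`.

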