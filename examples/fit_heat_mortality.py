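"""Estimate the heat-mortality relationship from a synthetic daily series.

Simulates five warm seasons of daily death counts with a known two-segment
temperature effect (threshold 19.7 deg C, +1.70 % mortality per deg C above
it), then recovers the relationship two ways: an exploratory cubic
regression spline and the segmented GEE model with maximum-likelihood
threshold.
"""

import numpy as np

from heatmort import (
    SeriesSpec,
    fit_spline_curve,
    fit_threshold_model,
    lag_mean_exposure,
    simulate_daily_series,
)

records = simulate_daily_series(SeriesSpec(seed=42))
exposure = lag_mean_exposure(records.set_index("date")["tmean_c"], policy="partial")

curve = fit_spline_curve(records, exposure, df=5)
print(f"spline curve minimum (minimum-mortality exposure): {curve.minimum:.1f} deg C")

fit = fit_threshold_model(records, exposure, estimation="iterative")
lo, hi = fit.threshold_ci()
print(f"threshold T0: {fit.threshold:.1f} deg C (90% CI {lo:.1f}; {hi:.1f})")
print(f"mortality change above T0: +{fit.percent_change_above():.2f} % per deg C")
print(f"mortality change below T0: +{fit.percent_change_below():.2f} % per deg C of cooling")
print(f"AR(1) working correlation: {fit.ar1_dep:.3f}; converged: {fit.converged}")
print()
print("The generating truths were T0 = 19.7, +1.70 %/C above, +4.11 %/C below;")
print("estimates differ from them only by sampling noise of a 5-summer series.")
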