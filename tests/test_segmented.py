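import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from heatmort import (
    SeriesSpec,
    build_design_matrix,
    fit_spline_curve,
    fit_threshold_model,
    lag_mean_exposure,
    percent_change_per_degree,
    simulate_daily_series,
)
from tests.conftest import make_noise_free_records


class TestPercentChange:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, 0.0), (np.log(1.0170), 1.70), (0.01, 1.0050167)],
    )
    def test_values(self, beta, expected):
        assert percent_change_per_degree(beta) == pytest.approx(expected, abs=1e-5)


class TestBuildDesignMatrix:
    def test_row_count_two_summers(self):
        rec = simulate_daily_series(SeriesSpec(n_summers=2, seed=3))
        expo = lag_mean_exposure(rec.set_index("date")["tmean_c"], policy="partial")
        data = build_design_matrix(rec, expo)
        assert len(data.X) == 306
        assert len(data.y) == 306

    def test_pm10_toggle_changes_columns_not_rows(self, default_series, default_exposure):
        with_pm = build_design_matrix(default_series, default_exposure, adjust_pm10=True)
        without = build_design_matrix(default_series, default_exposure, adjust_pm10=False)
        assert "pm10_lag01" in with_pm.X.columns
        assert "pm10_lag01" not in without.X.columns
        assert len(with_pm.X) == len(without.X)  # complete PM10: no rows dropped

    def test_expected_column_set(self, default_series, default_exposure):
        data = build_design_matrix(default_series, default_exposure, adjust_pm10=False)
        expected = (
            ["intercept", "holiday"]
            + [f"dow_{d}" for d in range(1, 7)]
            + [f"month_{m}" for m in range(6, 10)]
            + ["year_idx", "year_idx_sq", "dewpoint", "dewpoint_sq"]
        )
        assert list(data.X.columns) == expected

    def test_sunday_holiday_sets_both_dummies(self):
        # 2010-05-02 is a Sunday (dayofweek 6)
        dates = pd.date_range("2010-05-01", periods=8, freq="D")
        rec = pd.DataFrame(
            {
                "date": dates,
                "deaths": 5,
                "tmean_c": 20.0,
                "dewpoint_c": 10.0,
                "pm10": 40.0,
                "holiday": [0, 1, 0, 0, 0, 0, 0, 0],
            }
        )
        expo = pd.Series(20.0, index=dates)
        data = build_design_matrix(rec, expo)
        sunday_holiday = data.X.iloc[1]
        assert sunday_holiday["holiday"] == 1.0
        assert sunday_holiday["dow_6"] == 1.0

    def test_missing_pm10_interpolated_then_complete_case(self):
        rec = simulate_daily_series(SeriesSpec(n_summers=2, seed=4))
        rec.loc[10:11, "pm10"] = np.nan  # short gap: interpolated
        rec.loc[50:55, "pm10"] = np.nan  # long gap: dropped rows
        expo = lag_mean_exposure(rec.set_index("date")["tmean_c"], policy="partial")
        data = build_design_matrix(rec, expo, adjust_pm10=True)
        assert data.n_dropped > 0
        assert len(data.X) == 306 - data.n_dropped
        assert not data.X["pm10_lag01"].isna().any()

    def test_all_missing_pm10_rejected(self):
        rec = simulate_daily_series(SeriesSpec(n_summers=2, seed=5))
        rec["pm10"] = np.nan
        expo = lag_mean_exposure(rec.set_index("date")["tmean_c"], policy="partial")
        with pytest.raises(ValueError, match="PM10"):
            build_design_matrix(rec, expo, adjust_pm10=True)


class TestSplineCurve:
    def test_df_is_basis_dimension(self, default_series, default_exposure):
        curve = fit_spline_curve(default_series, default_exposure, df=5)
        assert curve.n_basis == 5

    def test_v_shape_minimum_recovered(self):
        """Strong V-shaped truth with minimum at 20 deg C, ~5000 days."""
        spec = SeriesSpec(
            n_summers=33,
            threshold_true=20.0,
            slope_below=-0.05,
            slope_above=0.05,
            seed=31,
        )
        rec = simulate_daily_series(spec)
        expo = lag_mean_exposure(rec.set_index("date")["tmean_c"], policy="partial")
        curve = fit_spline_curve(rec, expo)
        assert curve.minimum == pytest.approx(20.0, abs=1.0)

    def test_null_simulation_bands_cover_flat_truth(self):
        """No exposure effect: the pointwise 95 % bands must cover the flat
        truth at close to their nominal rate, averaged over the exposure
        range and replicates."""
        seeds = np.random.SeedSequence(41).generate_state(40)
        fracs = []
        for s in seeds:
            spec = SeriesSpec(
                n_summers=3,
                slope_below=0.0,
                slope_above=0.0,
                dependence_sd=0.0,
                seed=int(s) & 0x7FFFFFFF,
            )
            rec = simulate_daily_series(spec)
            expo = lag_mean_exposure(rec.set_index("date")["tmean_c"], policy="partial")
            curve = fit_spline_curve(rec, expo)
            # in the centred spline basis a flat truth has all-zero spline
            # coefficients, i.e. uncentred component 0 == centred -centre
            truth = -curve.centre
            fracs.append(np.mean((curve.lower <= truth) & (curve.upper >= truth)))
        assert 0.90 <= np.mean(fracs) <= 0.99

    def test_too_few_observations_rejected(self):
        rec = simulate_daily_series(SeriesSpec(n_summers=1, seed=6)).iloc[:40]
        expo = lag_mean_exposure(rec.set_index("date")["tmean_c"], policy="partial")
        with pytest.raises(ValueError, match="50 observations"):
            fit_spline_curve(rec, expo)


def brute_force_threshold(records, exposure, grid):
    """Independent grid-search oracle: direct Poisson GLM likelihood scan
    over candidate thresholds with a minimal hand-built design."""
    dates = pd.DatetimeIndex(records["date"])
    e = exposure.reindex(dates).to_numpy()
    y = records["deaths"].to_numpy(dtype=float)
    best_ll, best_t0 = -np.inf, None
    for c in grid:
        X = np.column_stack(
            [np.ones_like(e), e, np.where(e > c, e - c, 0.0)]
        )
        ll = sm.GLM(y, X, family=sm.families.Poisson()).fit().llf
        if ll > best_ll + 1e-12:
            best_ll, best_t0 = ll, c
    return best_t0


class TestThresholdModel:
    def test_noise_free_estimators_agree_with_grid_oracle(self):
        """On exact two-segment expected counts both estimators and a
        0.01 deg C brute-force likelihood scan locate the same break."""
        rec = make_noise_free_records(t0=20.0, beta1=-0.04, beta2=0.017)
        expo = lag_mean_exposure(rec.set_index("date")["tmean_c"], policy="partial")
        # the exposure is the generating variable here: use tmean_c directly
        expo = pd.Series(
            rec.set_index("date")["tmean_c"]
            .rolling(4, min_periods=1)
            .mean()
            .to_numpy(),
            index=pd.DatetimeIndex(rec["date"]),
        )
        grid = np.round(np.arange(18.0, 22.0 + 1e-9, 0.01), 2)
        oracle = brute_force_threshold(rec, expo, grid)
        fit_it = fit_threshold_model(rec, expo, adjust_pm10=False, estimation="iterative")
        fit_pr = fit_threshold_model(
            rec, expo, adjust_pm10=False, estimation="profile", grid_step=0.01
        )
        assert oracle == pytest.approx(20.0, abs=0.05)
        assert fit_it.threshold == pytest.approx(oracle, abs=0.05)
        assert fit_pr.threshold == pytest.approx(oracle, abs=0.05)
        assert fit_it.threshold == pytest.approx(fit_pr.threshold, abs=0.05)
        # slopes recovered essentially exactly on noise-free data
        assert fit_it.slope_below == pytest.approx(-0.04, abs=1e-3)
        assert fit_it.slope_above == pytest.approx(0.017, abs=1e-3)

    def test_profile_equals_exhaustive_search_on_own_grid(self):
        """Profile estimator is by construction an exhaustive scan: on its
        own grid it must match the independent oracle exactly."""
        rec = make_noise_free_records(t0=19.5, beta1=-0.035, beta2=0.02, seed=11)
        expo = pd.Series(
            rec.set_index("date")["tmean_c"].rolling(4, min_periods=1).mean().to_numpy(),
            index=pd.DatetimeIndex(rec["date"]),
        )
        fit = fit_threshold_model(
            rec, expo, adjust_pm10=False, estimation="profile", grid_step=0.1
        )
        e = expo.to_numpy()
        lo, hi = np.percentile(e, [5, 95])
        grid = np.arange(np.ceil(lo / 0.1), np.floor(hi / 0.1) + 1) * 0.1
        oracle = brute_force_threshold(rec, expo, grid)
        assert fit.threshold == oracle

    def test_percent_change_accessors(self, default_series, default_exposure):
        fit = fit_threshold_model(default_series, default_exposure)
        assert fit.percent_change_above() == pytest.approx(
            100 * (np.exp(fit.slope_above) - 1)
        )
        assert fit.percent_change_below() == pytest.approx(
            100 * (np.exp(-fit.slope_below) - 1)
        )

    def test_continuity_of_two_segment_predictor(self, default_series, default_exposure):
        """The join constraint: the fitted exposure term is continuous at T0."""
        fit = fit_threshold_model(default_series, default_exposure)
        t0 = fit.threshold
        eps = 1e-9
        below = fit.slope_below * (t0 - eps - t0)
        above = fit.slope_above * (t0 + eps - t0)
        assert below == pytest.approx(0.0, abs=1e-7)
        assert above == pytest.approx(0.0, abs=1e-7)

    def test_single_summer_rejected(self):
        rec = simulate_daily_series(SeriesSpec(n_summers=1, seed=8))
        expo = lag_mean_exposure(rec.set_index("date")["tmean_c"], policy="partial")
        with pytest.raises(ValueError, match="2 summers"):
            fit_threshold_model(rec, expo)

    def test_standard_errors_positive_when_converged(self, default_series, default_exposure):
        fit = fit_threshold_model(default_series, default_exposure)
        assert fit.converged
        assert fit.slope_above_se > 0
        assert fit.slope_below_se > 0
        assert fit.threshold_se > 0

    def test_null_slope_above_ci_covers_zero(self):
        """With beta2 = 0 above a nominal break, the 90 % CI for the
        slope above must cover 0 in about 90 % of replicates."""
        seeds = np.random.SeedSequence(53).generate_state(50)
        cover = []
        for s in seeds:
            spec = SeriesSpec(
                n_summers=5, slope_above=0.0, seed=int(s) & 0x7FFFFFFF
            )
            rec = simulate_daily_series(spec)
            expo = lag_mean_exposure(
                rec.set_index("date")["tmean_c"], policy="partial"
            )
            fit = fit_threshold_model(rec, expo)
            lo, hi = fit.slope_above_ci()
            cover.append(lo <= 0.0 <= hi)
        assert 0.78 <= np.mean(cover) <= 1.0
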