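import dataclasses

import numpy as np
import pandas as pd
import pytest

from heatmort import (
    ClimateScenario,
    HIAConfig,
    ScenarioSpec,
    attributable_deaths_expected,
    attributable_deaths_observed,
    attributable_fraction,
    estimate_gamma,
    fit_exponential,
    monte_carlo_impact,
    simulate_climate_ensemble,
)
from heatmort.segmented import SegmentedFit

BETA2 = float(np.log(1.0170))


def make_fit(threshold=19.7, slope_above=BETA2, threshold_se=0.7, slope_above_se=0.005):
    return SegmentedFit(
        threshold=threshold,
        threshold_se=threshold_se,
        slope_below=-0.04,
        slope_below_se=0.01,
        slope_above=slope_above,
        slope_above_se=slope_above_se,
        intercept=np.log(10.0),
        confounder_coefs={},
        fitted_means=np.array([]),
        converged=True,
    )


class TestAttributableFraction:
    def test_zero_below_threshold(self):
        assert attributable_fraction(15.0, 19.7, BETA2) == 0.0

    def test_zero_slope_gives_zero(self):
        assert attributable_fraction(25.0, 19.7, 0.0) == 0.0

    def test_two_degrees_above_at_sample_slope(self):
        # 1 - 1.0170**-2: relative-risk inversion at +2 deg C
        assert attributable_fraction(21.7, 19.7, BETA2) == pytest.approx(
            1.0 - 1.0170**-2, abs=1e-12
        )

    def test_monotone_nondecreasing_in_temperature(self):
        T = np.linspace(10, 40, 200)
        af = attributable_fraction(T, 19.7, BETA2)
        assert np.all(np.diff(af) >= 0)
        assert np.all(af[T <= 19.7] == 0)

    def test_negative_slope_not_truncated(self):
        assert attributable_fraction(25.0, 19.7, -0.01) < 0


class TestAttributableDeathsObserved:
    def test_zero_fractions(self):
        assert attributable_deaths_observed([5, 7, 9], np.zeros(3)) == 0.0

    def test_hand_sum(self):
        assert attributable_deaths_observed([100, 100], [0.1, 0.2]) == pytest.approx(30.0)

    def test_bounded_by_total_deaths(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(10, 153)
        af = rng.uniform(0, 0.99, 153)
        assert attributable_deaths_observed(y, af) <= y.sum()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            attributable_deaths_observed([1, 2], [0.1])


class TestAttributableDeathsExpected:
    def test_zero_fractions(self):
        cfg = HIAConfig()
        assert attributable_deaths_expected(500_000, cfg, np.zeros(153)) == 0.0

    def test_paper_constants_arithmetic(self):
        cfg = HIAConfig(crude_mortality_rate=0.0093, warm_season_death_fraction=0.385)
        # hand arithmetic: 500000 * 0.0093 * 0.385 * 0.045 = 80.56125
        out = attributable_deaths_expected(500_000, cfg, np.full(153, 0.045))
        assert out == pytest.approx(80.56125, abs=1e-9)

    def test_wrong_season_length(self):
        with pytest.raises(ValueError, match="153"):
            attributable_deaths_expected(500_000, HIAConfig(), np.zeros(100))

    def test_linear_in_population_rate_and_gamma(self):
        afs = np.full(153, 0.03)
        base = attributable_deaths_expected(100_000, HIAConfig(), afs)
        assert attributable_deaths_expected(200_000, HIAConfig(), afs) == pytest.approx(
            2 * base
        )
        cfg2 = HIAConfig(crude_mortality_rate=2 * 0.0093)
        assert attributable_deaths_expected(100_000, cfg2, afs) == pytest.approx(2 * base)

    def test_product_approximation_matches_daily_sum_oracle(self):
        """Eq-4-style product vs the exact daily-sum identity.

        When daily deaths are independent of the daily AFs, the expected
        attributable deaths P*r*gamma*mean(AF) must agree with the average
        over many years of sum(Y_i * AF_i).
        """
        rng = np.random.default_rng(99)
        n_years, mu = 500, 10.0
        cfg = HIAConfig()
        pop = mu * 153 / (cfg.crude_mortality_rate * cfg.warm_season_death_fraction)
        t0, beta2 = 19.7, BETA2
        per_year = []
        afs_all = []
        for _ in range(n_years):
            T = rng.normal(20.7, 4.0, 153)
            af = attributable_fraction(T, t0, beta2)
            y = rng.poisson(mu, 153)  # deaths independent of AF day-by-day
            per_year.append(attributable_deaths_observed(y, af))
            afs_all.append(af)
        oracle = np.mean(per_year)
        product = np.mean(
            [attributable_deaths_expected(pop, cfg, af) for af in afs_all]
        )
        assert product == pytest.approx(oracle, rel=0.02)


def test_baseline_climate_mean_af_in_plausibility_band():
    """At the study's point estimates (T0 = 19.7 deg C, +1.70 %/deg C) a
    synthetic baseline-climate ensemble (warm-season mean 20.7 deg C, 95th
    percentile 27.4 deg C) must yield a mean AF in the 2-5 % band."""
    (sc,) = simulate_climate_ensemble(
        [ScenarioSpec(target_mean=20.7, target_p95=27.4, start_year=2003,
                      n_years=20, seed=17)]
    )
    af = attributable_fraction(sc.warm_season_exposure().to_numpy(), 19.7, BETA2)
    assert 0.02 <= af.mean() <= 0.05


class TestEstimateGamma:
    @staticmethod
    def _uniform_year(year=2010, value=3):
        idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        return pd.Series(value, index=idx)

    def test_uniform_deaths(self):
        assert estimate_gamma(self._uniform_year()) == pytest.approx(153 / 365)

    def test_all_deaths_in_warm_season(self):
        s = self._uniform_year(value=0)
        s.loc["2010-07-01":"2010-07-10"] = 5
        assert estimate_gamma(s) == pytest.approx(1.0)

    def test_incomplete_year_raises_listing_span(self):
        s = self._uniform_year().drop(pd.Timestamp("2010-03-15"))
        with pytest.raises(ValueError, match="2010.*missing"):
            estimate_gamma(s)


@pytest.fixture(scope="module")
def scenario():
    (sc,) = simulate_climate_ensemble(
        [
            ScenarioSpec(
                target_mean=22.9,
                target_p95=30.0,
                model_label="median",
                period_label="2026-2045",
                start_year=2026,
                n_years=5,
                seed=3,
            )
        ]
    )
    return sc


class TestMonteCarloImpact:
    def test_zero_ses_collapse_to_point_estimate(self, scenario):
        fit = make_fit(threshold_se=0.0, slope_above_se=0.0)
        pop = fit_exponential(500_000, 520_000)
        cfg = HIAConfig(mc_draws=50, seed=5)
        dist = monte_carlo_impact(fit, scenario, pop, cfg)
        assert np.allclose(dist.per_year_ad, dist.per_year_ad[0][None, :])
        assert dist.q10 == pytest.approx(dist.mean_ad_per_year)
        assert dist.q90 == pytest.approx(dist.mean_ad_per_year)

    def test_seed_reproducibility_and_mc_stability(self, scenario):
        fit = make_fit()
        pop = fit_exponential(500_000, 520_000)
        a = monte_carlo_impact(fit, scenario, pop, HIAConfig(mc_draws=10_000, seed=1))
        b = monte_carlo_impact(fit, scenario, pop, HIAConfig(mc_draws=10_000, seed=1))
        assert np.array_equal(a.per_year_ad, b.per_year_ad)
        c = monte_carlo_impact(fit, scenario, pop, HIAConfig(mc_draws=10_000, seed=2))
        assert c.mean_ad_per_year == pytest.approx(a.mean_ad_per_year, rel=0.01)

    def test_quantile_ordering_per_year(self, scenario):
        fit = make_fit()
        pop = fit_exponential(500_000, 520_000)
        dist = monte_carlo_impact(fit, scenario, pop, HIAConfig(mc_draws=500, seed=8))
        q10y = np.quantile(dist.per_year_ad, 0.10, axis=0)
        q90y = np.quantile(dist.per_year_ad, 0.90, axis=0)
        assert np.all(q10y <= q90y)
        assert dist.q10 <= dist.q90

    def test_fixed_population_accepted(self, scenario):
        dist = monte_carlo_impact(
            make_fit(), scenario, 500_000.0, HIAConfig(mc_draws=20, seed=0)
        )
        assert dist.population_label == "fixed"

    def test_scenario_year_mismatch_with_population_anchor(self):
        (early,) = simulate_climate_ensemble(
            [
                ScenarioSpec(
                    target_mean=20.7,
                    target_p95=27.4,
                    period_label="1986-2005",
                    start_year=1986,
                    n_years=3,
                    seed=1,
                )
            ]
        )
        pop = fit_exponential(500_000, 520_000)  # anchored at 2002
        with pytest.raises(ValueError, match="population model anchored"):
            monte_carlo_impact(make_fit(), early, pop, HIAConfig(mc_draws=10, seed=0))

    def test_nonconverged_fit_rejected(self, scenario):
        fit = dataclasses.replace(make_fit(), converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            monte_carlo_impact(fit, scenario, 500_000.0, HIAConfig(mc_draws=10, seed=0))
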