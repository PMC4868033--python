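"""Attributable fractions and attributable deaths, with Monte Carlo
uncertainty propagation.

Under the two-segment log-linear model, the fraction of deaths on day *i*
attributable to exposure above the threshold is

    AF_i = 1 - 1 / exp(beta2 * (T_i - T0) * I(T_i > T0)),

zero at or below the threshold.  When daily death counts Y_i are observed,
attributable deaths are AD = sum_i Y_i * AF_i.  For projected periods,
where Y_i is unknown, the expected AD per warm season is approximated by

    AD = P * r * gamma * mean(AF_i)

with P the (projected) population, r the crude mortality rate, gamma the
fraction of annual deaths falling in the warm season, and the mean over the
n = 153 warm-season days.  The approximation is valid when day-by-day
correlation between death counts and AF is minimal, i.e. heat is not the
main determinant of the daily mortality level.

Sampling variability of the fitted (beta2, T0) is propagated by drawing
independently from Normal distributions centred at the point estimates with
the fitted standard errors; gamma and r are treated as known constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .exposure import WARM_SEASON_DAYS, lag_mean_exposure, warm_season_mask
from .population import PopulationModel, project_population
from .segmented import SegmentedFit

__all__ = [
    "HIAConfig",
    "ClimateScenario",
    "ImpactDistribution",
    "attributable_fraction",
    "attributable_deaths_observed",
    "attributable_deaths_expected",
    "estimate_gamma",
    "sample_parameter_draws",
    "monte_carlo_impact",
]


@dataclass(frozen=True)
class HIAConfig:
    """Constants of the health impact assessment.

    crude_mortality_rate
        Annual deaths per capita r (default 0.0093, i.e. 0.93 %).
    warm_season_death_fraction
        Fraction gamma of annual deaths falling in the warm season
        (default 0.385).
    """

    crude_mortality_rate: float = 0.0093
    warm_season_death_fraction: float = 0.385
    n_days: int = WARM_SEASON_DAYS
    mc_draws: int = 10_000
    seed: int = 0
    ci_quantiles: tuple[float, float] = (0.10, 0.90)
    #: "years_then_draws" (default): average per-year AD within each draw
    #: over the period, then summarise across draws.  "draws_then_years"
    #: summarises each year across draws first.
    summary_order: str = "years_then_draws"

    def __post_init__(self):
        if not 0 < self.crude_mortality_rate < 1:
            raise ValueError("crude_mortality_rate must be in (0, 1)")
        if not 0 < self.warm_season_death_fraction <= 1:
            raise ValueError("warm_season_death_fraction must be in (0, 1]")
        if self.mc_draws < 1:
            raise ValueError("mc_draws must be >= 1")
        if self.summary_order not in ("years_then_draws", "draws_then_years"):
            raise ValueError(f"unknown summary_order {self.summary_order!r}")


@dataclass
class ClimateScenario:
    """Daily mean temperature series labelled by climate model and period."""

    model_label: str
    period_label: str
    data: pd.DataFrame  # columns: date, tmean_c

    def __post_init__(self):
        self.data = self.data.copy()
        self.data["date"] = pd.DatetimeIndex(self.data["date"])
        self.data = self.data.sort_values("date").reset_index(drop=True)

    @property
    def years(self) -> np.ndarray:
        return np.unique(pd.DatetimeIndex(self.data["date"]).year)

    def warm_season_exposure(self, n_lags: int = 3) -> pd.Series:
        """Lag 0-3 exposure over the scenario's warm-season days."""
        s = self.data.set_index("date")["tmean_c"]
        return lag_mean_exposure(s, n_lags=n_lags, policy="carry_in")


@dataclass
class ImpactDistribution:
    """Monte Carlo sample of attributable deaths per year for one scenario."""

    per_year_ad: np.ndarray  # draws x years
    years: np.ndarray
    mean_ad_per_year: float
    q10: float
    q90: float
    mean_af: float  # mean AF at the point estimates
    model_label: str = ""
    period_label: str = ""
    population_label: str = ""


def attributable_fraction(T, T0: float, beta2: float):
    """Daily attributable fraction 1 - exp(-beta2 * (T - T0)) above T0.

    Zero at or below the threshold.  Negative beta2 yields negative
    fractions above the threshold; values are deliberately not truncated so
    that Monte Carlo draws keep their sampling distribution.
    """
    T = np.asarray(T, dtype=float)
    excess = np.where(T > T0, T - T0, 0.0)
    out = 1.0 - np.exp(-beta2 * excess)
    return float(out) if out.ndim == 0 else out


def attributable_deaths_observed(deaths, afs) -> float:
    """Attributable deaths from observed daily counts: sum(Y_i * AF_i)."""
    y = np.asarray(deaths, dtype=float)
    af = np.asarray(afs, dtype=float)
    if y.shape != af.shape:
        raise ValueError(f"length mismatch: deaths {y.shape} vs afs {af.shape}")
    return float(np.sum(y * af))


def attributable_deaths_expected(
    population: float, config: HIAConfig, afs
) -> float:
    """Expected warm-season attributable deaths: P * r * gamma * mean(AF)."""
    af = np.asarray(afs, dtype=float)
    if af.size != config.n_days:
        raise ValueError(
            f"expected one AF per warm-season day (n={config.n_days}), got {af.size}"
        )
    return (
        population
        * config.crude_mortality_rate
        * config.warm_season_death_fraction
        * float(np.mean(af))
    )


def estimate_gamma(full_year_deaths: pd.Series) -> float:
    """Fraction of deaths falling in the warm season, from complete years.

    The input must span whole calendar years of daily death counts; any
    missing day makes the ratio ill-defined and raises an error listing the
    missing spans.
    """
    s = pd.Series(full_year_deaths).copy()
    s.index = pd.DatetimeIndex(s.index)
    s = s.sort_index()
    problems = []
    for year, block in s.groupby(s.index.year):
        expected = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        missing = expected.difference(block.index)
        if len(missing):
            problems.append(f"{year}: {len(missing)} missing days from {missing[0].date()}")
    if problems:
        raise ValueError("incomplete calendar years: " + "; ".join(problems))
    total = float(s.sum())
    if total == 0:
        raise ValueError("no deaths in the series")
    warm = float(s[warm_season_mask(s.index)].sum())
    return warm / total


def sample_parameter_draws(
    fit: SegmentedFit, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent Normal draws of (beta2*, T0*) around the fit.

    Returns an (n_draws, 2) array; the first column is beta2.  Drawing once
    and reusing the array across scenarios/population models keeps the
    "heat-mortality draw" a single factor in the sensitivity decomposition.
    """
    beta2 = rng.normal(fit.slope_above, fit.slope_above_se, size=n_draws)
    t0 = rng.normal(fit.threshold, fit.threshold_se, size=n_draws)
    return np.column_stack([beta2, t0])


def monte_carlo_impact(
    fit: SegmentedFit,
    scenario: ClimateScenario,
    popmodel: Union[PopulationModel, float],
    config: HIAConfig,
    draws: Optional[np.ndarray] = None,
) -> ImpactDistribution:
    """Propagate (beta2, T0) sampling uncertainty into AD per year.

    For each draw and each scenario year, daily AFs are computed on the
    year's lag 0-3 exposure and converted to expected attributable deaths
    with the year's projected population (or a fixed population when
    ``popmodel`` is a number).  Draws may be supplied to share the
    parameter sample across scenarios; otherwise they are generated from
    ``config.seed``.
    """
    if not fit.converged:
        raise ValueError("refusing to propagate a non-converged fit")
    if draws is None:
        rng = np.random.default_rng(config.seed)
        draws = sample_parameter_draws(fit, config.mc_draws, rng)
    draws = np.asarray(draws, dtype=float)
    years = scenario.years
    exposure = scenario.warm_season_exposure()
    exp_years = pd.DatetimeIndex(exposure.index).year

    if isinstance(popmodel, PopulationModel):
        try:
            pops = project_population(popmodel, years)
        except ValueError as exc:
            raise ValueError(
                f"scenario years {years.min()}-{years.max()} incompatible with "
                f"population model anchored at {popmodel.anchor_year}: {exc}"
            ) from exc
        pop_label = popmodel.label
    else:
        pops = np.full(years.shape, float(popmodel))
        pop_label = "fixed"

    n_draws = draws.shape[0]
    ad = np.empty((n_draws, years.size))
    mean_af_point = 0.0
    rg = config.crude_mortality_rate * config.warm_season_death_fraction
    for j, (year, pop) in enumerate(zip(years, pops)):
        T = exposure.to_numpy()[exp_years == year]
        if T.size != config.n_days:
            raise ValueError(
                f"scenario year {year} has {T.size} warm-season days, "
                f"expected {config.n_days}"
            )
        # mean AF per draw: vectorised over draws x days
        excess = np.clip(T[None, :] - draws[:, 1][:, None], 0.0, None)
        af = 1.0 - np.exp(-draws[:, 0][:, None] * excess)
        ad[:, j] = pop * rg * af.mean(axis=1)
        mean_af_point += float(
            np.mean(attributable_fraction(T, fit.threshold, fit.slope_above))
        )
    mean_af_point /= years.size

    qlo, qhi = config.ci_quantiles
    if config.summary_order == "years_then_draws":
        per_draw = ad.mean(axis=1)  # average over the period's years first
        mean_ad = float(per_draw.mean())
        q10, q90 = (float(q) for q in np.quantile(per_draw, [qlo, qhi]))
    else:
        per_year_mean = ad.mean(axis=0)
        mean_ad = float(per_year_mean.mean())
        q10 = float(np.mean(np.quantile(ad, qlo, axis=0)))
        q90 = float(np.mean(np.quantile(ad, qhi, axis=0)))
    return ImpactDistribution(
        per_year_ad=ad,
        years=years,
        mean_ad_per_year=mean_ad,
        q10=q10,
        q90=q90,
        mean_af=mean_af_point,
        model_label=scenario.model_label,
        period_label=scenario.period_label,
        population_label=pop_label,
    )
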