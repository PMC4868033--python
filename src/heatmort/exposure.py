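"""Exposure indicators for warm-season heat-mortality analysis.

The exposure driving daily mortality is the lag 0-3 mean temperature: the
average of the daily mean temperature on the current day and the three
preceding days.  Analyses are restricted to the warm season (1 May - 30
September, 153 days), the operating window of heat early-warning systems.
An apparent-temperature variant combining air temperature and dew point is
provided for comparison with the heat-epidemiology literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WARM_SEASON_START",
    "WARM_SEASON_END",
    "WARM_SEASON_DAYS",
    "warm_season_mask",
    "warm_season_filter",
    "lag_mean_exposure",
    "apparent_temperature",
    "city_mean",
    "compare_series",
    "SeriesComparison",
]

#: (month, day) bounds of the warm season, inclusive.
WARM_SEASON_START = (5, 1)
WARM_SEASON_END = (9, 30)
#: Number of calendar days in [1 May, 30 September] — the same every year.
WARM_SEASON_DAYS = 153


def warm_season_mask(dates: pd.DatetimeIndex) -> np.ndarray:
    """Boolean mask selecting dates whose month-day falls in the warm season."""
    dates = pd.DatetimeIndex(dates)
    md = dates.month * 100 + dates.day
    lo = WARM_SEASON_START[0] * 100 + WARM_SEASON_START[1]
    hi = WARM_SEASON_END[0] * 100 + WARM_SEASON_END[1]
    return np.asarray((md >= lo) & (md <= hi))


def warm_season_filter(dates: pd.DatetimeIndex) -> pd.DatetimeIndex:
    """Retain exactly the dates with month-day in [05-01, 09-30].

    An empty selection is allowed.
    """
    dates = pd.DatetimeIndex(dates)
    return dates[warm_season_mask(dates)]


def _check_contiguous(dates: pd.DatetimeIndex, context: str) -> None:
    if len(dates) < 2:
        return
    gaps = np.diff(dates.values).astype("timedelta64[D]").astype(int)
    bad = np.nonzero(gaps != 1)[0]
    if bad.size:
        i = bad[0]
        raise ValueError(
            f"non-contiguous dates within {context}: gap between "
            f"{dates[i].date()} and {dates[i + 1].date()}"
        )


def lag_mean_exposure(
    daily_temps: pd.Series,
    n_lags: int = 3,
    policy: str = "carry_in",
) -> pd.Series:
    """Lag 0-``n_lags`` mean of a daily temperature series.

    The value on day *i* is the mean of days ``i, i-1, ..., i-n_lags``.
    Two boundary policies govern the first days of each summer:

    ``"carry_in"``
        Pre-season days present in the input (e.g. late April) contribute to
        the rolling mean; the output is then restricted to the warm season.
        When no pre-season days are supplied the first days fall back to the
        mean of the available lags.
    ``"partial"``
        The input is restricted to the warm season *before* averaging, so the
        first ``n_lags`` days of each summer average only the days available
        within the season.

    Parameters
    ----------
    daily_temps
        Series of daily mean temperatures indexed by date, contiguous within
        each summer block (one block per calendar year).
    n_lags
        Number of preceding days entering the average (default 3).
    policy
        ``"carry_in"`` or ``"partial"``.

    Returns
    -------
    pandas.Series
        Warm-season exposure values named ``"lag0_{n_lags}_tmean"``.
    """
    if policy not in ("carry_in", "partial"):
        raise ValueError(f"unknown boundary policy: {policy!r}")
    s = pd.Series(daily_temps).copy()
    s.index = pd.DatetimeIndex(s.index)
    s = s.sort_index()
    if policy == "partial":
        s = s[warm_season_mask(s.index)]
    out = []
    for year, block in s.groupby(s.index.year):
        _check_contiguous(block.index, f"summer {year}")
        roll = block.rolling(window=n_lags + 1, min_periods=1).mean()
        out.append(roll[warm_season_mask(roll.index)])
    res = pd.concat(out) if out else pd.Series(dtype=float)
    res.name = f"lag0_{n_lags}_tmean"
    return res


def apparent_temperature(
    t_air,
    t_dew,
    coefs: tuple[float, float, float] = (-2.653, 0.994, 0.0153),
):
    """Apparent temperature from air temperature and dew point (deg C).

    AT = c0 + c1 * t_air + c2 * t_dew**2, with the standard coefficients of
    the European heat-epidemiology (PHEWE-family) studies by default.
    """
    c0, c1, c2 = coefs
    return c0 + c1 * np.asarray(t_air, dtype=float) + c2 * np.asarray(t_dew, dtype=float) ** 2


def city_mean(grid_series: pd.DataFrame) -> pd.Series:
    """Unweighted daily mean over all grid cells within the city boundary.

    Parameters
    ----------
    grid_series
        Long-format frame with columns ``date``, ``cell_id``, ``tmean_c``:
        one daily series per grid cell, all cells sharing the same dates.
    """
    required = {"date", "cell_id", "tmean_c"}
    missing = required - set(grid_series.columns)
    if missing:
        raise ValueError(f"grid series missing columns: {sorted(missing)}")
    wide = grid_series.pivot(index="date", columns="cell_id", values="tmean_c")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"cells missing on dates: {bad}")
    out = wide.mean(axis=1)
    out.name = "tmean_c"
    return out


@dataclass(frozen=True)
class SeriesComparison:
    """Pearson correlation and mean bias between modelled and measured series."""

    pearson_r: float
    mean_bias: float
    #: False when either series has zero variance (correlation undefined).
    r_defined: bool = True


def compare_series(modelled, measured) -> SeriesComparison:
    """Compare a modelled daily series against measurements.

    Returns the Pearson correlation coefficient and the mean bias
    ``mean(modelled - measured)``.  Series must be aligned, of equal length
    >= 3.  If either series is constant the correlation is undefined and
    flagged via ``r_defined=False``.
    """
    a = np.asarray(modelled, dtype=float)
    b = np.asarray(measured, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError("need at least 3 aligned observations")
    bias = float(np.mean(a - b))
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return SeriesComparison(pearson_r=float("nan"), mean_bias=bias, r_defined=False)
    r, _ = stats.pearsonr(a, b)
    return SeriesComparison(pearson_r=float(r), mean_bias=bias)
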