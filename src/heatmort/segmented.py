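"""Heat-mortality exposure-response estimation.

Daily death counts y_i are modelled as Poisson with log mean

    log(lambda_i) = alpha + confounders
                    + beta1 * (T_i - T0) * I(T_i <= T0)
                    + beta2 * (T_i - T0) * I(T_i > T0)

where T_i is the lag 0-3 mean temperature, T0 the threshold of minimum
mortality where the two linear segments join, and beta1/beta2 the log-scale
slopes below/above the threshold.  The confounder block contains dummies for
holidays, day of week and calendar month, a quadratic long-term trend in a
0-based year index, a quadratic in dew point, and optionally the lag 0-1
mean of PM10.

Estimation combines a maximum-likelihood threshold search (Muggeo's
iterative linearization, or an exhaustive profile-likelihood grid) with a
generalized-estimating-equations fit of the final model: summers are
independent clusters with a first-order autoregressive working correlation
for the within-summer counts, and model-based ("naive") standard errors are
used, as recommended when clusters are few and large.

An exploratory cubic-regression-spline curve of log relative mortality
against exposure, with pointwise confidence bands, is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Autoregressive, Independence

from .exposure import warm_season_mask

__all__ = [
    "DesignData",
    "SegmentedFit",
    "SplineCurve",
    "build_design_matrix",
    "fit_spline_curve",
    "fit_threshold_model",
    "percent_change_per_degree",
]

logger = logging.getLogger(__name__)

REQUIRED_RECORD_COLUMNS = ("date", "deaths", "tmean_c", "dewpoint_c", "holiday")


def percent_change_per_degree(beta) -> float:
    """Percent change in mortality per 1 deg C: 100 * (exp(beta) - 1)."""
    return 100.0 * np.expm1(np.asarray(beta, dtype=float))


@dataclass
class DesignData:
    """Aligned design matrix, response and clustering metadata for one fit."""

    X: pd.DataFrame
    y: np.ndarray
    exposure: np.ndarray
    groups: np.ndarray  # summer (cluster) labels
    time: np.ndarray  # day index within each summer
    dates: pd.DatetimeIndex
    n_dropped: int = 0


def _pm10_lag01(records: pd.DataFrame) -> pd.Series:
    """Mean of current and previous day PM10, after short-gap interpolation.

    Within each summer, gaps of at most 2 consecutive missing days are
    linearly interpolated; longer gaps stay missing (complete-case handling
    happens in the design assembly).  The first day of a summer uses the
    current day only.
    """
    out = []
    pm = records.set_index("date")["pm10"].astype(float)
    for _, block in pm.groupby(pm.index.year):
        filled = block.interpolate(method="linear", limit=2, limit_area="inside")
        prev = filled.shift(1)
        lag01 = (filled + prev) / 2.0
        lag01.iloc[0] = filled.iloc[0]
        out.append(lag01)
    return pd.concat(out)


def build_design_matrix(
    records: pd.DataFrame,
    exposure: pd.Series,
    adjust_pm10: bool = True,
) -> DesignData:
    """Assemble the confounder design matrix and response.

    Parameters
    ----------
    records
        Daily health records with columns ``date, deaths, tmean_c,
        dewpoint_c, pm10, holiday`` (``pm10`` may be missing, and may be
        absent entirely when ``adjust_pm10`` is False).
    exposure
        Lag 0-3 exposure series indexed by date; must align with the
        warm-season dates of ``records``.
    adjust_pm10
        Include the lag 0-1 PM10 term.  Missing PM10 is linearly
        interpolated over gaps of <= 2 days; remaining incomplete rows are
        dropped (complete-case) with a logged count.

    Returns
    -------
    DesignData
        Columns: intercept; holiday; day-of-week dummies (Monday
        reference); month dummies (May reference); 0-based year index,
        linear and quadratic; dew point, linear and quadratic; optionally
        lag 0-1 PM10.  The exposure term is handled by the fitters.
    """
    missing = [c for c in REQUIRED_RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    rec = records.copy()
    rec["date"] = pd.DatetimeIndex(rec["date"])
    rec = rec.sort_values("date").reset_index(drop=True)
    rec = rec[warm_season_mask(pd.DatetimeIndex(rec["date"]))].reset_index(drop=True)

    exposure = pd.Series(exposure).copy()
    exposure.index = pd.DatetimeIndex(exposure.index)
    aligned = exposure.reindex(pd.DatetimeIndex(rec["date"]))
    if aligned.isna().any():
        bad = aligned.index[aligned.isna()][:5].tolist()
        raise ValueError(f"exposure missing for record dates, e.g. {bad}")

    dates = pd.DatetimeIndex(rec["date"])
    X = pd.DataFrame(index=rec.index)
    X["intercept"] = 1.0
    X["holiday"] = rec["holiday"].astype(float).to_numpy()
    dow = dates.dayofweek  # Monday=0 is the reference level
    for d in range(1, 7):
        X[f"dow_{d}"] = (dow == d).astype(float)
    for m in range(6, 10):  # May is the reference month
        X[f"month_{m}"] = (dates.month == m).astype(float)
    year_idx = (dates.year - dates.year.min()).astype(float)
    X["year_idx"] = year_idx
    X["year_idx_sq"] = year_idx**2
    dew = rec["dewpoint_c"].astype(float).to_numpy()
    X["dewpoint"] = dew
    X["dewpoint_sq"] = dew**2

    keep = np.ones(len(rec), dtype=bool)
    n_dropped = 0
    if adjust_pm10:
        if "pm10" not in rec.columns:
            raise ValueError("adjust_pm10=True but records have no 'pm10' column")
        pm_lag = _pm10_lag01(rec).reindex(dates).to_numpy()
        if np.all(np.isnan(pm_lag)):
            raise ValueError("PM10 column is entirely missing")
        keep = ~np.isnan(pm_lag)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d rows with unrecoverable missing PM10", n_dropped)
        X["pm10_lag01"] = pm_lag

    y = rec["deaths"].astype(float).to_numpy()
    groups = dates.year.to_numpy()
    time = pd.Series(groups).groupby(groups).cumcount().to_numpy()
    return DesignData(
        X=X.loc[keep].reset_index(drop=True),
        y=y[keep],
        exposure=aligned.to_numpy()[keep],
        groups=groups[keep],
        time=time[keep],
        dates=dates[keep],
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Exploratory spline curve


@dataclass
class SplineCurve:
    """Fitted log-relative-mortality curve with pointwise confidence bands.

    The curve is centred at its minimum, so values are log relative risks
    with respect to the minimum-mortality exposure; the bands are pointwise
    bands of the uncentred curve shifted by the same centring constant.
    """

    grid: np.ndarray
    log_rr: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_basis: int
    ci_level: float = 0.95
    #: constant subtracted to centre the curve at its minimum; the uncentred
    #: spline component is ``log_rr + centre``
    centre: float = 0.0

    @property
    def minimum(self) -> float:
        """Exposure value at the curve minimum."""
        return float(self.grid[np.argmin(self.log_rr)])


def fit_spline_curve(
    records: pd.DataFrame,
    exposure: pd.Series,
    df: int = 5,
    adjust_pm10: bool = True,
    ci_level: float = 0.95,
    n_grid: int = 151,
) -> SplineCurve:
    """Flexible exposure-response curve via a cubic regression spline.

    The exposure enters the confounder-adjusted Poisson model through a
    natural cubic regression spline basis with ``df`` degrees of freedom,
    the knots placed on the quantiles of the exposure distribution.
    """
    data = build_design_matrix(records, exposure, adjust_pm10=adjust_pm10)
    if len(data.y) < 50:
        raise ValueError("need at least 50 observations for the spline curve")
    # mgcv-style centred (sum-to-zero) cubic regression spline basis: df
    # columns, knots on the quantiles, full rank alongside the intercept.
    basis = patsy.dmatrix(
        "cr(x, df=df, constraints='center') - 1",
        {"x": data.exposure, "df": df},
        return_type="dataframe",
    )
    if basis.shape[1] != df:
        raise ValueError(f"spline basis has {basis.shape[1]} columns, expected {df}")
    Xfull = np.column_stack([data.X.to_numpy(), basis.to_numpy()])
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        raise ValueError("singular design with this spline basis; try fewer df")
    res = sm.GLM(data.y, Xfull, family=sm.families.Poisson()).fit()
    k = data.X.shape[1]
    coef_spline = res.params[k:]
    cov_spline = res.cov_params()[k:, k:]

    grid = np.linspace(data.exposure.min(), data.exposure.max(), n_grid)
    (bgrid,) = patsy.build_design_matrices([basis.design_info], {"x": grid, "df": df})
    B = np.asarray(bgrid)
    eta = B @ coef_spline
    se = np.sqrt(np.einsum("ij,jk,ik->i", B, cov_spline, B))
    from scipy.stats import norm

    z = norm.ppf(0.5 + ci_level / 2.0)
    shift = eta.min()
    return SplineCurve(
        grid=grid,
        log_rr=eta - shift,
        lower=eta - z * se - shift,
        upper=eta + z * se - shift,
        n_basis=int(basis.shape[1]),
        ci_level=ci_level,
        centre=float(shift),
    )


# ---------------------------------------------------------------------------
# Segmented (threshold) model


@dataclass
class SegmentedFit:
    """Fitted two-segment heat-mortality model.

    Slopes are on the log scale per deg C; the model-based (naive) GEE
    standard errors feed the Monte Carlo impact propagation.
    """

    threshold: float
    threshold_se: float
    slope_below: float
    slope_below_se: float
    slope_above: float
    slope_above_se: float
    intercept: float
    confounder_coefs: dict
    fitted_means: np.ndarray
    ci_level: float = 0.90
    converged: bool = True
    boundary_pinned: bool = False
    estimation: str = "iterative"
    n_iter: int = 0
    n_obs: int = 0
    n_dropped: int = 0
    ar1_dep: float = 0.0
    slope_cov: float = 0.0  # naive covariance of (slope_below, slope_above)

    def percent_change_above(self) -> float:
        """Percent change in mortality per +1 deg C above the threshold."""
        return percent_change_per_degree(self.slope_above)

    def percent_change_below(self) -> float:
        """Percent change in mortality per -1 deg C below the threshold."""
        return percent_change_per_degree(-self.slope_below)

    def _ci(self, est: float, se: float) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + self.ci_level / 2.0)
        return est - z * se, est + z * se

    def threshold_ci(self) -> tuple[float, float]:
        return self._ci(self.threshold, self.threshold_se)

    def slope_above_ci(self) -> tuple[float, float]:
        return self._ci(self.slope_above, self.slope_above_se)

    def to_dict(self) -> dict:
        return {
            "threshold_c": self.threshold,
            "threshold_se_c": self.threshold_se,
            "slope_below": self.slope_below,
            "slope_below_se": self.slope_below_se,
            "slope_above": self.slope_above,
            "slope_above_se": self.slope_above_se,
            "pct_change_above_per_c": self.percent_change_above(),
            "pct_change_below_per_c": self.percent_change_below(),
            "intercept": self.intercept,
            "confounder_coefs": self.confounder_coefs,
            "ci_level": self.ci_level,
            "converged": self.converged,
            "boundary_pinned": self.boundary_pinned,
            "estimation": self.estimation,
            "n_iter": self.n_iter,
            "n_obs": self.n_obs,
            "n_dropped_missing_pm10": self.n_dropped,
            "ar1_dep": self.ar1_dep,
        }


def _segment_columns(e: np.ndarray, t0: float, with_gap: bool) -> np.ndarray:
    """Exposure columns at a candidate threshold.

    ``e`` linear, ``U = (e - t0)+`` (slope difference above the break) and,
    when ``with_gap``, Muggeo's gap regressor ``V = -I(e > t0)`` whose
    coefficient measures the discontinuity left by the linearization.
    """
    above = e > t0
    U = (e - t0) * above
    if with_gap:
        return np.column_stack([e, U, -above.astype(float)])
    return np.column_stack([e, U])


def _poisson_glm(y, X):
    return sm.GLM(y, X, family=sm.families.Poisson()).fit()


def _muggeo_search(
    data: DesignData,
    t0_init: float,
    lo: float,
    hi: float,
    tol: float,
    max_iter: int,
) -> tuple[float, bool, int]:
    """Muggeo iterative linearization for the break point on the Poisson ML.

    At each step refit with the slope-difference term U and the gap term V at
    the current break, then move the break by gamma_hat / delta_hat (the gap
    coefficient over the slope difference).  The profile likelihood has kinks
    at the observed exposures, so the raw iteration can enter a two-cycle
    around the optimum; the step is damped by a persistent factor halved on
    every direction reversal, and the converged break is polished by a fine
    local profile search (0.01 deg C grid within the last oscillation
    bracket) so the returned value is the local ML point.
    """
    Xc = data.X.to_numpy()
    t0 = float(np.clip(t0_init, lo, hi))
    prev_step = None
    damping = 1.0
    converged = False
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        seg = _segment_columns(data.exposure, t0, with_gap=True)
        res = _poisson_glm(data.y, np.column_stack([Xc, seg]))
        delta = res.params[-2]
        gamma = res.params[-1]
        if not np.isfinite(delta) or abs(delta) < 1e-12:
            return t0, False, it
        step = gamma / delta
        if prev_step is not None and step * prev_step < 0:
            damping *= 0.5
        applied = damping * step
        new = float(np.clip(t0 + applied, lo, hi))
        moved = abs(new - t0)
        t0, prev_step = new, step
        if moved < tol:
            converged, n_iter = True, it
            break
    # Local polish: the linearized update lands between likelihood kinks;
    # take the profile-ML point within the bracket the iteration explored.
    half_width = max(0.5, abs(prev_step)) if prev_step is not None else 0.5
    g_lo = max(lo, t0 - half_width)
    g_hi = min(hi, t0 + half_width)
    grid = np.arange(g_lo, g_hi + 1e-12, 0.01)
    if grid.size:
        ll = np.empty(grid.size)
        for i, c in enumerate(grid):
            seg = _segment_columns(data.exposure, c, with_gap=False)
            ll[i] = _poisson_glm(data.y, np.column_stack([Xc, seg])).llf
        t0 = float(grid[int(np.argmax(ll))])
    return t0, converged, n_iter


def _profile_search(
    data: DesignData,
    lo: float,
    hi: float,
    grid_step: float,
) -> tuple[float, float, bool]:
    """Exhaustive profile-likelihood grid search for the break point.

    Returns the grid argmax (ties broken toward the lower candidate), a
    curvature-based standard error from a local quadratic through the three
    central points, and a boundary flag.
    """
    Xc = data.X.to_numpy()
    # Round endpoints onto a grid of multiples of grid_step for reproducibility.
    grid = np.arange(np.ceil(lo / grid_step), np.floor(hi / grid_step) + 1) * grid_step
    if grid.size == 0:
        raise ValueError("empty threshold search grid; widen the exposure range")
    ll = np.empty(grid.size)
    for i, c in enumerate(grid):
        seg = _segment_columns(data.exposure, c, with_gap=False)
        ll[i] = _poisson_glm(data.y, np.column_stack([Xc, seg])).llf
    best = int(np.argmax(ll))  # argmax returns the first (lowest) maximiser
    t0 = float(grid[best])
    pinned = best in (0, grid.size - 1)
    se = float("nan")
    if not pinned:
        d2 = (ll[best - 1] - 2 * ll[best] + ll[best + 1]) / grid_step**2
        if d2 < 0:
            se = float(1.0 / np.sqrt(-d2))
    return t0, se, pinned


def fit_threshold_model(
    records: pd.DataFrame,
    exposure: pd.Series,
    adjust_pm10: bool = True,
    estimation: str = "iterative",
    ci_level: float = 0.90,
    grid_step: float = 0.1,
    tol: float = 1e-4,
    max_iter: int = 50,
    working_correlation: str = "ar1",
) -> SegmentedFit:
    """Fit the segmented two-slope Poisson model with ML threshold.

    The threshold maximises the Poisson likelihood — via Muggeo's iterative
    linearization (``estimation="iterative"``, default, initialised at the
    exposure median) or an exhaustive profile grid search between the 5th
    and 95th exposure percentiles (``estimation="profile"``).  Slopes and
    their model-based standard errors come from a GEE fit at the selected
    threshold with summers as clusters and an AR(1) working correlation.

    Returns a :class:`SegmentedFit`; non-convergence is reported through
    ``converged=False`` and a threshold pinned at the search boundary
    through ``boundary_pinned=True``.
    """
    if estimation not in ("iterative", "profile"):
        raise ValueError(f"unknown estimation method {estimation!r}")
    data = build_design_matrix(records, exposure, adjust_pm10=adjust_pm10)
    if len(np.unique(data.groups)) < 2:
        raise ValueError("need at least 2 summers to estimate the model")
    e = data.exposure
    lo, hi = np.percentile(e, [5, 95])
    pinned = False
    n_iter = 0
    profile_se = float("nan")
    if estimation == "iterative":
        t0, converged, n_iter = _muggeo_search(
            data, float(np.median(e)), lo, hi, tol, max_iter
        )
        pinned = t0 <= lo + tol or t0 >= hi - tol
    else:
        t0, profile_se, pinned = _profile_search(data, lo, hi, grid_step)
        converged = True

    # Final GEE fit at the selected threshold, gap term included so the
    # threshold SE follows from Muggeo's delta method on (gamma, delta).
    seg = _segment_columns(e, t0, with_gap=True)
    Xfull = np.column_stack([data.X.to_numpy(), seg])
    names = list(data.X.columns) + ["exposure", "seg_diff", "gap"]
    if working_correlation == "ar1":
        cov_struct = Autoregressive(grid=True)
    elif working_correlation == "independence":
        cov_struct = Independence()
    else:
        raise ValueError(f"unknown working correlation {working_correlation!r}")
    model = sm.GEE(
        data.y,
        Xfull,
        groups=data.groups,
        time=data.time[:, None],
        family=sm.families.Poisson(),
        cov_struct=cov_struct,
    )
    try:
        res = model.fit(maxiter=100)
        gee_ok = True
    except Exception as exc:  # noqa: BLE001 - surfaced via diagnostics
        logger.warning("GEE fit failed (%s); falling back to GLM covariance", exc)
        res = _poisson_glm(data.y, Xfull)
        gee_ok = False

    params = dict(zip(names, res.params))
    if gee_ok:
        cov = np.asarray(res.cov_naive)
    else:
        cov = np.asarray(res.cov_params())
    i_e, i_u, i_v = len(names) - 3, len(names) - 2, len(names) - 1
    beta1 = params["exposure"]
    delta = params["seg_diff"]
    gamma = params["gap"]
    beta2 = beta1 + delta
    var_b1 = cov[i_e, i_e]
    var_b2 = cov[i_e, i_e] + cov[i_u, i_u] + 2 * cov[i_e, i_u]
    cov_b1b2 = cov[i_e, i_e] + cov[i_e, i_u]
    # Delta-method variance of t0 = gamma/delta (gamma ~ 0 at convergence).
    g = np.array([1.0 / delta, -gamma / delta**2])
    sub = cov[np.ix_([i_v, i_u], [i_v, i_u])]
    var_t0 = float(g @ sub @ g)
    t0_se = np.sqrt(var_t0) if var_t0 > 0 else float("nan")
    if estimation == "profile" and not np.isfinite(t0_se):
        t0_se = profile_se

    confounders = {
        k: float(v)
        for k, v in params.items()
        if k not in ("intercept", "exposure", "seg_diff", "gap")
    }
    return SegmentedFit(
        threshold=float(t0),
        threshold_se=float(t0_se),
        slope_below=float(beta1),
        slope_below_se=float(np.sqrt(var_b1)),
        slope_above=float(beta2),
        slope_above_se=float(np.sqrt(var_b2)),
        intercept=float(params["intercept"]),
        confounder_coefs=confounders,
        fitted_means=np.asarray(res.fittedvalues, dtype=float),
        ci_level=ci_level,
        converged=bool(converged and gee_ok),
        boundary_pinned=bool(pinned),
        estimation=estimation,
        n_iter=n_iter,
        n_obs=len(data.y),
        n_dropped=data.n_dropped,
        ar1_dep=float(np.atleast_1d(getattr(res, "cov_struct", cov_struct).dep_params)[0])
        if gee_ok and working_correlation == "ar1"
        else 0.0,
        slope_cov=float(cov_b1b2),
    )
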