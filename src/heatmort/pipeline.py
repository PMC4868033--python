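"""End-to-end orchestration: fit, project, impact, sensitivity.

``run_pipeline`` executes the whole health impact assessment from a single
:class:`PipelineConfig`: estimate the segmented heat-mortality relationship
from the (real or synthetic) daily series, propagate the fitted parameters
through the climate scenarios and population projections by Monte Carlo,
and decompose the variance of the projected attributable deaths into its
sources.  It writes a fit report (JSON), a tidy impact summary plus a
mean-(q10; q90) impact table (CSV), a total-effect-index table (CSV), and a
run log carrying the seed, package version and input hashes, so a run is
reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import apparent_temperature, lag_mean_exposure
from .impact import (
    ClimateScenario,
    HIAConfig,
    ImpactDistribution,
    attributable_deaths_observed,
    attributable_fraction,
    monte_carlo_impact,
    sample_parameter_draws,
)
from .io import read_health_csv, read_scenario_csv
from .population import DEFAULT_K_LIST, fit_exponential, fit_logistic
from .segmented import SegmentedFit, fit_threshold_model
from .sensitivity import FactorGrid, total_effect_index
from .synthetic import ScenarioSpec, SeriesSpec, simulate_climate_ensemble, simulate_daily_series

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one source per input slot."""

    seed: int = 0
    output_dir: Union[str, Path, None] = None
    # input slots: a CSV path or a synthetic spec (not both)
    health_csv: Optional[str] = None
    health_spec: Optional[SeriesSpec] = None
    scenario_csv: Optional[str] = None
    scenario_specs: Optional[Sequence[ScenarioSpec]] = None
    #: period label identifying the baseline (single-climate) period
    baseline_period: Optional[str] = None
    exposure_indicator: str = "tmean"  # "tmean" | "apparent"
    lag_policy: str = "carry_in"
    adjust_pm10: bool = True
    estimation: str = "iterative"
    hia: HIAConfig = field(default_factory=HIAConfig)
    # population anchors (the census values are inputs, not constants)
    p_anchor: float = 500_000
    anchor_year: int = 2002
    p_second: float = 520_000
    second_year: int = 2012
    k_list: Sequence[float] = DEFAULT_K_LIST

    def __post_init__(self):
        if (self.health_csv is None) == (self.health_spec is None):
            raise ValueError("provide exactly one of health_csv / health_spec")
        if self.scenario_csv is not None and self.scenario_specs is not None:
            raise ValueError("provide at most one of scenario_csv / scenario_specs")
        if self.exposure_indicator not in ("tmean", "apparent"):
            raise ValueError(f"unknown exposure indicator {self.exposure_indicator!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hia" in raw:
            raw["hia"] = HIAConfig(**raw["hia"])
        if "health_spec" in raw and raw["health_spec"] is not None:
            raw["health_spec"] = SeriesSpec(**raw["health_spec"])
        if "scenario_specs" in raw and raw["scenario_specs"] is not None:
            raw["scenario_specs"] = [ScenarioSpec(**s) for s in raw["scenario_specs"]]
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run produced."""

    fit: SegmentedFit
    sample_period: dict
    impacts: list[ImpactDistribution]
    impact_summary: Optional[pd.DataFrame]
    sensitivity: Optional[pd.DataFrame]
    run_log: dict


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def _build_exposure(records: pd.DataFrame, config: PipelineConfig) -> pd.Series:
    s = records.set_index("date")
    if config.exposure_indicator == "apparent":
        base = pd.Series(
            apparent_temperature(s["tmean_c"], s["dewpoint_c"]), index=s.index
        )
    else:
        base = s["tmean_c"]
    return lag_mean_exposure(base, policy=config.lag_policy)


@_stage("impact")
def _impact_stage(fit, scenarios, config, mc_seed):
    popmodels = [
        fit_exponential(
            config.p_anchor, config.p_second, config.anchor_year, config.second_year
        )
    ] + [
        fit_logistic(
            config.p_anchor, config.p_second, k, config.anchor_year, config.second_year
        )
        for k in config.k_list
    ]
    draws = sample_parameter_draws(
        fit, config.hia.mc_draws, np.random.default_rng(mc_seed)
    )
    impacts = []
    for sc in scenarios:
        for pm in popmodels:
            impacts.append(monte_carlo_impact(fit, sc, pm, config.hia, draws=draws))
    return impacts


def _impact_tables(impacts) -> tuple[pd.DataFrame, pd.DataFrame]:
    tidy = pd.DataFrame(
        {
            "period": [d.period_label for d in impacts],
            "climate_model": [d.model_label for d in impacts],
            "population_model": [d.population_label for d in impacts],
            "mean_af": [d.mean_af for d in impacts],
            "mean_ad_per_year": [d.mean_ad_per_year for d in impacts],
            "q10": [d.q10 for d in impacts],
            "q90": [d.q90 for d in impacts],
        }
    )
    cells = tidy.assign(
        cell=[
            f"{m:.0f} ({lo:.0f}; {hi:.0f})"
            for m, lo, hi in zip(tidy["mean_ad_per_year"], tidy["q10"], tidy["q90"])
        ]
    )
    table2 = cells.pivot(
        index="population_model", columns=["period", "climate_model"], values="cell"
    )
    return tidy, table2


@_stage("sensitivity")
def _sensitivity_stage(impacts, baseline_period) -> pd.DataFrame:
    """Total-effect indices per period from the full-factorial AD outputs."""
    rows = {}
    by_period: dict[str, list[ImpactDistribution]] = {}
    for d in impacts:
        by_period.setdefault(d.period_label, []).append(d)
    for period, dists in by_period.items():
        if period == baseline_period:
            # Baseline: single climate model; climate/population factors absent.
            d = dists[0]
            n_draws, n_years = d.per_year_ad.shape
            grid = FactorGrid(
                data=pd.DataFrame(
                    {
                        "draw": np.repeat(np.arange(n_draws), n_years),
                        "year": np.tile(d.years, n_draws),
                        "ad": d.per_year_ad.ravel(),
                    }
                ),
                factors=("draw", "year"),
            )
            rows[period] = {
                "heat_mortality_draw": total_effect_index(grid, "draw"),
                "inter_annual": total_effect_index(grid, "year"),
                "climate_model": np.nan,
                "population_model": np.nan,
            }
        else:
            frames = []
            for d in dists:
                n_draws, n_years = d.per_year_ad.shape
                frames.append(
                    pd.DataFrame(
                        {
                            "draw": np.repeat(np.arange(n_draws), n_years),
                            "year": np.tile(d.years, n_draws),
                            "climate": d.model_label,
                            "population": d.population_label,
                            "ad": d.per_year_ad.ravel(),
                        }
                    )
                )
            grid = FactorGrid(
                data=pd.concat(frames, ignore_index=True),
                factors=("draw", "year", "climate", "population"),
            )
            rows[period] = {
                "heat_mortality_draw": total_effect_index(grid, "draw"),
                "inter_annual": total_effect_index(grid, "year"),
                "climate_model": total_effect_index(grid, "climate"),
                "population_model": total_effect_index(grid, "population"),
            }
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute fit -> project -> impact -> sensitivity.

    Returns the in-memory result bundle and, when ``config.output_dir`` is
    set, writes ``fit.json``, ``impact_summary.csv``, ``table_ad.csv``,
    ``table_sensitivity.csv`` and ``run_log.json`` there.  Stages without
    inputs (no climate scenarios) are skipped with a logged notice.
    """
    master = np.random.SeedSequence(config.seed)
    health_seed, mc_seed, scen_seed = (
        int(s) & 0x7FFFFFFF for s in master.generate_state(3)
    )

    # --- data stage
    try:
        if config.health_csv is not None:
            records = read_health_csv(config.health_csv)
        else:
            spec = config.health_spec
            spec.seed = health_seed
            records = simulate_daily_series(spec)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'data' failed: {exc}") from exc

    # --- fit stage
    try:
        exposure = _build_exposure(records, config)
        fit = fit_threshold_model(
            records,
            exposure,
            adjust_pm10=config.adjust_pm10,
            estimation=config.estimation,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    # Sample-period impact from the observed counts (AF/AD identities).
    warm_exp = exposure.reindex(pd.DatetimeIndex(records["date"])).to_numpy()
    afs = attributable_fraction(warm_exp, fit.threshold, fit.slope_above)
    n_summers = pd.DatetimeIndex(records["date"]).year.nunique()
    ad_total = attributable_deaths_observed(records["deaths"].to_numpy(), afs)
    sample_period = {
        "mean_af": float(np.mean(afs)),
        "af_weighted_by_deaths": ad_total / float(records["deaths"].sum()),
        "ad_per_year": ad_total / n_summers,
        "n_summers": int(n_summers),
    }

    # --- scenario stage
    scenarios: list[ClimateScenario] = []
    if config.scenario_csv is not None:
        scenarios = read_scenario_csv(config.scenario_csv)
    elif config.scenario_specs is not None:
        specs = list(config.scenario_specs)
        children = np.random.SeedSequence(scen_seed).spawn(len(specs))
        for sp, child in zip(specs, children):
            sp.seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
        scenarios = simulate_climate_ensemble(specs)

    impacts: list[ImpactDistribution] = []
    impact_summary = table2 = sens = None
    if scenarios:
        impacts = _impact_stage(fit, scenarios, config, mc_seed)
        impact_summary, table2 = _impact_tables(impacts)
        sens = _sensitivity_stage(impacts, config.baseline_period)
    else:
        logger.info("no climate scenarios configured; impact and sensitivity skipped")

    import statsmodels

    run_log = {
        "seed": config.seed,
        "heatmort_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "statsmodels_version": statsmodels.__version__,
        "n_records": int(len(records)),
        "health_input_hash": _hash_frame(records),
        "estimation": config.estimation,
        "exposure_indicator": config.exposure_indicator,
        "n_scenarios": len(scenarios),
        "mc_draws": config.hia.mc_draws,
        "stages_run": ["data", "fit"]
        + (["impact", "sensitivity"] if scenarios else []),
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "fit.json", "w") as fh:
            json.dump({"fit": fit.to_dict(), "sample_period": sample_period}, fh, indent=2)
        if impact_summary is not None:
            impact_summary.to_csv(out / "impact_summary.csv", index=False)
            table2.to_csv(out / "table_ad.csv")
            sens_pct = (100.0 * sens).round(2)
            sens_pct.to_csv(out / "table_sensitivity.csv", na_rep="-")
        with open(out / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=2)

    return PipelineResult(
        fit=fit,
        sample_period=sample_period,
        impacts=impacts,
        impact_summary=impact_summary,
        sensitivity=sens,
        run_log=run_log,
    )
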