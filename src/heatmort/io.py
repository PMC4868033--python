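"""CSV readers and writers for the pipeline's plain-text interchange formats.

All files are comma-separated UTF-8 with ISO-8601 dates and empty cells for
missing values.

* daily health series: ``date, deaths, tmean_c, dewpoint_c, pm10, holiday``
* climate scenario series: ``date, tmean_c, model_label, period_label``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .impact import ClimateScenario

__all__ = [
    "HEALTH_COLUMNS",
    "read_health_csv",
    "write_health_csv",
    "read_scenario_csv",
    "write_scenario_csv",
]

HEALTH_COLUMNS = ("date", "deaths", "tmean_c", "dewpoint_c", "pm10", "holiday")


def read_health_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a daily health series.

    Parameters
    ----------
    path
        CSV file with the columns of :data:`HEALTH_COLUMNS`.
    column_map
        Optional mapping from the file's column names to the canonical
        names, for externally produced files.

    Returns
    -------
    pandas.DataFrame
        Date-sorted records; missing PM10 cells preserved as NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in HEALTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
        bad = np.nonzero(parsed.isna().to_numpy())[0]
        # +2: 1-based rows plus the header line
        raise ValueError(
            f"{path.name}: unparseable date at file row(s) {[int(i) + 2 for i in bad[:5]]}"
        ) from None
    dup = df["date"][df["date"].duplicated()]
    if len(dup):
        raise ValueError(
            f"{path.name}: duplicated dates {[d.date().isoformat() for d in dup[:5]]}"
        )
    df = df.sort_values("date").reset_index(drop=True)
    df["deaths"] = df["deaths"].astype(int)
    if (df["deaths"] < 0).any():
        raise ValueError(f"{path.name}: negative death counts")
    df["holiday"] = df["holiday"].astype(int)
    return df[list(HEALTH_COLUMNS)]


def write_health_csv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")


def read_scenario_csv(path) -> list[ClimateScenario]:
    """Read labelled scenario series; one scenario per (model, period) pair."""
    df = pd.read_csv(path)
    required = {"date", "tmean_c", "model_label", "period_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    out = []
    for (model, period), block in df.groupby(["model_label", "period_label"], sort=False):
        out.append(
            ClimateScenario(
                model_label=str(model),
                period_label=str(period),
                data=block[["date", "tmean_c"]],
            )
        )
    return out


def write_scenario_csv(scenarios, path) -> None:
    frames = []
    for sc in scenarios:
        block = sc.data.copy()
        block["model_label"] = sc.model_label
        block["period_label"] = sc.period_label
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
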