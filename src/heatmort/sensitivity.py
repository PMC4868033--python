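"""Variance-based sensitivity analysis of the impact projections.

The contribution of each uncertainty source (sampling variability of the
heat-mortality parameters, inter-annual variability, climate model,
population model) to the variance of AD per year is measured by the
total-effect index

    S_Ti = E(Var(Y | X_~i)) / Var(Y) = 1 - Var(E(Y | X_~i)) / Var(Y)

where X_~i denotes all factors except X_i.  Because the pipeline evaluates
AD on a full-factorial grid (every parameter draw crossed with every year,
climate model and population model), the conditional moments are computed
exactly by grouping over the complement factors — no Saltelli-type sampling
design is needed.  Population (ddof=0) variances make the two algebraic
forms of the identity agree exactly on any finite grid.

Total-effect indices include interaction contributions, so they need not
sum to 1: the excess over 1 is the shared interaction variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FactorGrid", "total_effect_index", "total_effect_table"]


@dataclass
class FactorGrid:
    """Full-factorial outputs: one AD value per factor combination."""

    data: pd.DataFrame
    factors: tuple[str, ...]
    response: str = "ad"

    def __post_init__(self):
        missing = [c for c in (*self.factors, self.response) if c not in self.data.columns]
        if missing:
            raise ValueError(f"grid missing columns: {missing}")
        n_expected = int(np.prod([self.data[f].nunique() for f in self.factors]))
        if len(self.data) != n_expected:
            raise ValueError(
                f"grid is not full-factorial: {len(self.data)} rows, "
                f"expected {n_expected} (one per factor combination)"
            )


def total_effect_index(grid: FactorGrid, factor: str) -> float:
    """Total-effect index of one factor on the grid response.

    ``S_T = 1 - Var(mean of Y within each complement-factor cell) / Var(Y)``,
    equivalently the expected within-cell variance over the total variance.
    Raises when the total variance is zero (index undefined).
    """
    if factor not in grid.factors:
        raise ValueError(f"unknown factor {factor!r}; grid has {grid.factors}")
    y = grid.data[grid.response].to_numpy(dtype=float)
    var_total = float(np.var(y))  # ddof=0: population variance
    if var_total == 0.0:
        raise ValueError("total variance is zero; total-effect index undefined")
    complement = [f for f in grid.factors if f != factor]
    if not complement:
        return 1.0
    cell_means = grid.data.groupby(complement, observed=True)[grid.response].mean()
    # Full factorial => equal cell sizes, so the unweighted variance of the
    # cell means is Var(E(Y | X_~i)).
    var_explained = float(np.var(cell_means.to_numpy(dtype=float)))
    return 1.0 - var_explained / var_total


def total_effect_table(grid: FactorGrid) -> pd.Series:
    """Total-effect index for every factor, as fractions of total variance."""
    return pd.Series(
        {f: total_effect_index(grid, f) for f in grid.factors}, name="total_effect"
    )
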