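"""Population growth models calibrated to two census anchor points.

Two deterministic laws are supported, each passing exactly through both
anchors (this is a two-point calibration, not a least-squares fit):

* exponential — constant yearly growth rate,
  ``P(t) = P_a * (1 + rho)**(t - t_a)`` with
  ``rho = (P_b / P_a)**(1 / (t_b - t_a)) - 1``;
* logistic — growth bounded by a carrying capacity ``K``,
  ``P(t) = K / (1 + A * exp(-rho * (t - t_a)))`` with ``A = K / P_a - 1``
  and ``rho`` solved in closed form from the second anchor.

Exponential projections are reliable in the short-medium term; the logistic
family expresses long-horizon saturation scenarios through ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["PopulationModel", "fit_exponential", "fit_logistic", "project_population"]

#: Default carrying-capacity grid (persons) for logistic scenario sweeps.
DEFAULT_K_LIST = (700_000, 800_000, 900_000, 1_000_000)


@dataclass(frozen=True)
class PopulationModel:
    """A calibrated growth law anchored at two census points."""

    kind: str  # "exponential" | "logistic"
    anchor_year: int
    p_anchor: float
    second_year: int
    p_second: float
    derived_rate: float
    carrying_capacity: Optional[float] = None

    @property
    def label(self) -> str:
        if self.kind == "logistic":
            return f"logistic_K={int(self.carrying_capacity)}"
        return self.kind

    def project(self, year):
        return project_population(self, year)


def _check_anchors(p_anchor: float, p_second: float) -> None:
    if p_anchor <= 0 or p_second <= 0:
        raise ValueError(
            f"anchor populations must be positive, got {p_anchor} and {p_second}"
        )


def fit_exponential(
    p_anchor: float,
    p_second: float,
    anchor_year: int = 2002,
    second_year: int = 2012,
) -> PopulationModel:
    """Calibrate the constant-growth-rate model to two census points."""
    _check_anchors(p_anchor, p_second)
    if second_year <= anchor_year:
        raise ValueError("second_year must be after anchor_year")
    span = second_year - anchor_year
    rate = (p_second / p_anchor) ** (1.0 / span) - 1.0
    return PopulationModel(
        kind="exponential",
        anchor_year=anchor_year,
        p_anchor=float(p_anchor),
        second_year=second_year,
        p_second=float(p_second),
        derived_rate=rate,
    )


def fit_logistic(
    p_anchor: float,
    p_second: float,
    carrying_capacity: float,
    anchor_year: int = 2002,
    second_year: int = 2012,
) -> PopulationModel:
    """Calibrate the logistic law to two census points for a given K.

    Requires ``K > max(p_anchor, p_second)``; both anchors are reproduced
    exactly by the closed-form solution for the intrinsic rate.
    """
    _check_anchors(p_anchor, p_second)
    if second_year <= anchor_year:
        raise ValueError("second_year must be after anchor_year")
    K = float(carrying_capacity)
    if K <= max(p_anchor, p_second):
        raise ValueError(
            f"carrying capacity K={K} must exceed both anchors "
            f"({p_anchor}, {p_second})"
        )
    span = second_year - anchor_year
    A = K / p_anchor - 1.0
    # Solve K / (1 + A exp(-rho span)) = p_second for rho.
    rate = -np.log((K / p_second - 1.0) / A) / span
    return PopulationModel(
        kind="logistic",
        anchor_year=anchor_year,
        p_anchor=float(p_anchor),
        second_year=second_year,
        p_second=float(p_second),
        derived_rate=float(rate),
        carrying_capacity=K,
    )


def project_population(model: PopulationModel, year):
    """Evaluate the calibrated law at (possibly fractional) years.

    Years before the anchor year are rejected: the models are calibrated
    forward from the census anchor and are not back-cast.
    """
    t = np.asarray(year, dtype=float)
    if np.any(t < model.anchor_year):
        raise ValueError(
            f"year {np.min(t)} precedes anchor year {model.anchor_year}"
        )
    dt = t - model.anchor_year
    if model.kind == "exponential":
        out = model.p_anchor * (1.0 + model.derived_rate) ** dt
    elif model.kind == "logistic":
        K = model.carrying_capacity
        A = K / model.p_anchor - 1.0
        out = K / (1.0 + A * np.exp(-model.derived_rate * dt))
    else:  # pragma: no cover - constructor guards the kinds
        raise ValueError(f"unknown model kind {model.kind!r}")
    return float(out) if np.isscalar(year) else out
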