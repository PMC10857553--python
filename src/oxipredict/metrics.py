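"""Forecast error metrics and the composite fitness used to rank models.

The fitness aggregates four error measures of a saturation forecaster,

    fit = MaxAE / alpha + beta * MSE + gamma * MAPE + delta * MAE

with lower values better. MaxAE is divided by its weight (it is on a much
coarser scale than the mean errors), while MSE, MAPE and MAE are multiplied
by theirs. The default weights are alpha=5, beta=2.5, gamma=1.67, delta=1.25.
MAPE is expressed in percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "FitnessParams", "compute_metrics", "fitness"]


@dataclass(frozen=True)
class MetricsReport:
    """MAE, MSE, MAPE (percent), MaxAE, over ``n`` evaluated pairs."""

    mae: float
    mse: float
    mape: float
    max_ae: float
    n: int

    def __post_init__(self) -> None:
        for name in ("mae", "mse", "mape", "max_ae"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_ae < self.mae:
            raise ValueError("max_ae cannot be smaller than mae")
        if self.n < 1:
            raise ValueError("n must be at least 1")

    def to_json(self, params: "FitnessParams | None" = None) -> str:
        d = {
            "mae": self.mae,
            "mse": self.mse,
            "mape": self.mape,
            "max_ae": self.max_ae,
            "n": self.n,
        }
        if params is not None:
            d["fitness"] = fitness(self, params)
        return json.dumps(d)


@dataclass(frozen=True)
class FitnessParams:
    """Positive weights (alpha, beta, gamma, delta) of the composite fitness."""

    alpha: float = 5.0
    beta: float = 2.5
    gamma: float = 1.67
    delta: float = 1.25

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """MAE, MSE, MAPE and MaxAE of predictions against true saturations.

    ``y_true`` must be strictly positive (MAPE divides by it).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    if y_true.size < 1:
        raise ValueError("need at least one evaluated pair")
    if np.any(y_true == 0):
        raise ValueError("y_true contains zero: MAPE is undefined")
    err = np.abs(y_true - y_pred)
    return MetricsReport(
        mae=float(err.mean()),
        mse=float((err**2).mean()),
        mape=float(100.0 * (err / np.abs(y_true)).mean()),
        max_ae=float(err.max()),
        n=int(y_true.size),
    )


def fitness(report: MetricsReport, params: FitnessParams = FitnessParams()) -> float:
    """Composite fitness score; lower is better."""
    return (
        report.max_ae / params.alpha
        + params.beta * report.mse
        + params.gamma * report.mape
        + params.delta * report.mae
    )
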