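"""Breslow baseline cumulative hazard and derived survival curves.

Given a fitted time-dependent relative-risk function g(t, x), the hazard is
h(t|x) = h0(t) exp g(t, x).  The Breslow estimator places a hazard increment
at every unique event time t_i:

    dH0(t_i) = e_i / sum_{j: t_j >= t_i} exp g(t_i, x_j),

re-evaluating g at t_i for every at-risk subject (the time-dependent form).
With g = 0 this reduces to the Nelson-Aalen estimator.  Tied events share
one increment with a common risk-set denominator (Breslow tie handling).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurvivalDataset

__all__ = ["BaselineHazard", "SurvivalCurve", "breslow_fit", "predict_survival",
           "median_survival_time"]


@dataclass
class SurvivalCurve:
    """Right-continuous step survival function on an event-time grid."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.survival = np.asarray(self.survival, dtype=np.float64)
        if len(self.times) != len(self.survival):
            raise ValueError("times and survival must have equal length")

    def at(self, t: float) -> float:
        """S(t): 1 before the first grid time, last step value after."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


@dataclass
class BaselineHazard:
    """Sorted unique event times and non-negative hazard increments."""

    event_times: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=np.float64)
        self.increments = np.asarray(self.increments, dtype=np.float64)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.increments < 0) or not np.all(np.isfinite(self.increments)):
            raise ValueError("increments must be finite and non-negative")

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "increment": self.increments})

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "BaselineHazard":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["increment"].to_numpy())


def _risk_matrix(model, times: np.ndarray, data: SurvivalDataset) -> np.ndarray:
    """g evaluated on the (time, subject) grid; models expose .risk_matrix."""
    if hasattr(model, "risk_matrix"):
        return np.asarray(model.risk_matrix(times, data), dtype=np.float64)
    return np.asarray(model(times, data), dtype=np.float64)


def breslow_fit(model, train: SurvivalDataset) -> BaselineHazard:
    """Estimate the baseline cumulative-hazard increments on training data."""
    if train.n_events == 0:
        raise ValueError("cannot fit a baseline hazard with no events")
    event_t = train.t[train.d == 1]
    uniq, counts = np.unique(event_t, return_counts=True)
    G = _risk_matrix(model, uniq, train)  # (k, n)
    at_risk = train.t[None, :] >= uniq[:, None]
    denom = np.where(at_risk, np.exp(G), 0.0).sum(axis=1)
    return BaselineHazard(uniq, counts / denom)


def predict_survival(model, hazard: BaselineHazard,
                     data: SurvivalDataset) -> list[SurvivalCurve]:
    """Per-patient survival curves S(t|x) = exp(-sum dH0(t_i) exp g(t_i, x))."""
    G = _risk_matrix(model, hazard.event_times, data)  # (k, n)
    cumhaz = np.cumsum(hazard.increments[:, None] * np.exp(G), axis=0)
    S = np.exp(-cumhaz)
    return [SurvivalCurve(hazard.event_times, S[:, j]) for j in range(data.n)]


def median_survival_time(curve: SurvivalCurve) -> tuple[float, bool]:
    """Smallest grid time with S(t) <= 0.5; falls back to the last grid time.

    Returns (days, crossed); crossed is False when the curve never reaches
    0.5, in which case the reported time is a lower bound on the median.
    """
    if len(curve.times) == 0:
        raise ValueError("empty survival curve")
    below = np.flatnonzero(curve.survival <= 0.5)
    if below.size:
        return float(curve.times[below[0]]), True
    return float(curve.times[-1]), False
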