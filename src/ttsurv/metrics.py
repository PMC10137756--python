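"""Evaluation metrics for censored survival predictions.

The concordance index follows the strict pairwise form

    C = sum_{i,j} 1[T_j < T_i] 1[eta_j > eta_i] delta_j
        / sum_{i,j} 1[T_j < T_i] delta_j,

so tied risk scores earn no credit by default (Harrell's half-credit for
ties is available behind a flag).  The MAE averages |y - y_hat| over
patients with an observed event only; censored records carry no usable
ground-truth time and are excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .breslow import SurvivalCurve

__all__ = ["c_index", "mae_uncensored", "kaplan_meier", "logrank_test",
           "EvaluationReport"]


def c_index(times, risks, events, tie_credit: bool = False) -> float:
    """Concordance index over ordered pairs (i, j) with T_j < T_i, delta_j=1."""
    T = np.asarray(times, dtype=np.float64)
    eta = np.asarray(risks, dtype=np.float64)
    d = np.asarray(events)
    if not (len(T) == len(eta) == len(d)):
        raise ValueError("times, risks, events must have equal length")
    earlier = T[None, :] < T[:, None]          # [i, j]: T_j < T_i
    comparable = earlier & (d[None, :] == 1)   # j must be an observed event
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    higher = eta[None, :] > eta[:, None]       # eta_j > eta_i
    num = float((comparable & higher).sum())
    if tie_credit:
        num += 0.5 * float((comparable & (eta[None, :] == eta[:, None])).sum())
    return num / n_pairs


def mae_uncensored(true_days, predicted_days, events) -> float:
    """Mean absolute error in days over patients with an observed event."""
    y = np.asarray(true_days, dtype=np.float64)
    yhat = np.asarray(predicted_days, dtype=np.float64)
    d = np.asarray(events)
    mask = d == 1
    if not mask.any():
        raise ValueError("MAE undefined with zero observed events")
    return float(np.abs(y[mask] - yhat[mask]).mean())


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - e_i / n_i)."""
    T = np.asarray(times, dtype=np.float64)
    d = np.asarray(events)
    if len(T) == 0:
        raise ValueError("need at least one observation")
    uniq = np.unique(T[d == 1])
    if uniq.size == 0:
        return SurvivalCurve(np.unique(T), np.ones(len(np.unique(T))))
    at_risk = (T[None, :] >= uniq[:, None]).sum(axis=1)
    n_ev = ((T[None, :] == uniq[:, None]) & (d[None, :] == 1)).sum(axis=1)
    return SurvivalCurve(uniq, np.cumprod(1.0 - n_ev / at_risk))


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """K-sample log-rank test; returns (chi-square statistic, p-value).

    Observed-minus-expected event counts per group with the hypergeometric
    covariance at each event time; p is asymptotic on (K-1) df.
    """
    T = np.asarray(times, dtype=np.float64)
    d = np.asarray(events)
    g = np.asarray(group_labels)
    groups = np.unique(g)
    K = len(groups)
    if K < 2:
        raise ValueError("log-rank test needs at least two groups")
    if d.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    member = g[None, :] == groups[:, None]  # (K, n)
    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    for t in np.unique(T[d == 1]):
        at_risk = T >= t
        n = at_risk.sum()
        ev = int(((T == t) & (d == 1)).sum())
        n_k = (member & at_risk).sum(axis=1).astype(float)
        O += ((member & at_risk) & ((T == t) & (d == 1))).sum(axis=1)
        E += ev * n_k / n
        if n > 1:
            p = n_k / n
            V += ev * (n - ev) / (n - 1) * (np.diag(p) - np.outer(p, p))
    diff = (O - E)[:-1]
    stat = float(diff @ np.linalg.pinv(V[:-1, :-1]) @ diff)
    pval = float(stats.chi2.sf(stat, K - 1))
    return stat, pval


@dataclass
class EvaluationReport:
    """Per-fold C-index / MAE values and their mean."""

    fold_c_index: list[float] = field(default_factory=list)
    fold_mae_days: list[float] = field(default_factory=list)
    fold_n_events: list[int] = field(default_factory=list)

    @property
    def c_index(self) -> float:
        return float(np.mean(self.fold_c_index))

    @property
    def mae_days(self) -> float:
        return float(np.mean(self.fold_mae_days))

    @property
    def n_events_used(self) -> int:
        return int(np.sum(self.fold_n_events))
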