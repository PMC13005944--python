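"""Kaplan–Meier estimation, restricted mean survival time, and survival metrics.

The product-limit estimator and the RMST integral are implemented directly
(they are evaluated thousands of times inside the reinforcement-learning
loop and must stay allocation-light); the log-rank test and Harrell's
concordance index delegate to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

__all__ = [
    "KMCurve",
    "RmstConfig",
    "km_curve",
    "rmst",
    "rmst_by_group",
    "rmst_gap_reward",
    "logrank_score",
    "concordance_index",
]

_P_FLOOR = 1e-300  # log-rank P values below this are clipped before -log10


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve on the grid of distinct observed times.

    ``surv[i]`` is the survival probability just after ``times[i]`` (the
    curve is right-continuous); ``at_risk[i]`` and ``deaths[i]`` are the
    risk-set size and event count at ``times[i]``.  Time zero with S=1 is
    implicit and not stored.
    """

    times: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray

    def __post_init__(self) -> None:
        if self.times.size == 0:
            raise ValueError("empty Kaplan-Meier curve")
        if np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival probabilities must be nonincreasing")


@dataclass(frozen=True)
class RmstConfig:
    """Restriction horizon for the RMST integral, in months (default 60)."""

    t_restrict: float = 60.0

    def __post_init__(self) -> None:
        if self.t_restrict <= 0:
            raise ValueError("t_restrict must be positive")


def km_curve(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    Successive survival probabilities follow s_{t+1} = s_t * (1 - d_t/n_t),
    where d_t counts deaths at time t and n_t the subjects still at risk.
    Censored subjects leave the risk set after their censoring time and
    never contribute to d_t.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("km_curve requires at least one subject")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("survival times must be nonnegative")

    order = np.argsort(t, kind="stable")
    t = t[order]
    e = e[order]
    uniq, start = np.unique(t, return_index=True)
    n = t.size
    # at-risk count at each distinct time = subjects with time >= that time
    at_risk = n - start
    deaths = np.add.reduceat(e, start)
    with np.errstate(invalid="ignore"):
        factors = 1.0 - deaths / at_risk
    surv = np.cumprod(factors)
    return KMCurve(times=uniq, surv=surv, at_risk=at_risk.astype(int), deaths=deaths.astype(int))


def rmst(curve: KMCurve, cfg: RmstConfig = RmstConfig()) -> float:
    """Area under the KM step function on [0, t_restrict].

    The curve is extended flat beyond the last observed time; the integral
    is an exact rectangle sum over the event-time grid.
    """
    L = cfg.t_restrict
    # segment boundaries: 0, t_1, ..., t_M, L (times capped at L)
    t_cap = np.minimum(curve.times, L)
    left = np.concatenate(([0.0], t_cap))
    right = np.concatenate((t_cap, [L]))
    s = np.concatenate(([1.0], curve.surv))
    return float(np.sum((right - left) * s))


def rmst_by_group(times, events, groups, k: int, t_restrict: float = 60.0):
    """RMST per group for groups coded 0..k-1.

    Returns an array of length k; entries for empty groups are NaN.
    Fast path used by the training loop.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    g = np.asarray(groups)
    out = np.full(k, np.nan)
    for s in range(k):
        mask = g == s
        if not mask.any():
            continue
        out[s] = rmst(km_curve(t[mask], e[mask]), RmstConfig(t_restrict))
    return out


def rmst_gap_reward(tau) -> float:
    """Minimum pairwise RMST gap tau_a - tau_b over ordered pairs a < b.

    Subtypes are indexed so that a smaller index means a better prognosis;
    the reward is positive iff every better-labelled subtype has strictly
    larger RMST than every worse-labelled one.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.size < 2:
        raise ValueError("rmst_gap_reward needs at least two subtypes")
    gaps = tau[:, None] - tau[None, :]
    iu = np.triu_indices(tau.size, k=1)
    return float(np.min(gaps[iu]))


def logrank_score(groups, times, events) -> float:
    """-log10 P of the k-group log-rank chi-square test.

    1.3 corresponds to P = 0.05; higher means stronger prognostic
    separation between the groups.
    """
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("log-rank test requires at least two nonempty groups")
    res = multivariate_logrank_test(np.asarray(times, float), g, np.asarray(events, float))
    p = max(float(res.p_value), _P_FLOOR)
    return -np.log10(p)


def concordance_index(score, times, events) -> float:
    """Harrell's C for a higher-is-better-prognosis score.

    Fraction of comparable subject pairs whose score ordering matches the
    observed survival ordering; ties count 0.5.  0.5 is random, 1.0 perfect.
    """
    return float(_lifelines_cindex(np.asarray(times, float), np.asarray(score, float), np.asarray(events, float)))
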