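"""Nonparametric survival estimation.

Kaplan-Meier product-limit estimator of S(t), Nelson-Aalen estimator of
the cumulative hazard H(t), Greenwood's variance for pointwise confidence
intervals, and a synthetic-cohort version of the DHS component survival
probabilities over the standard age segments
0, 1-2, 3-5, 6-11, 12-23, 24-35, 36-47, 48-59 months.

With k distinct death times t_1 <= ... <= t_k, d_i deaths at t_i and q_i
children at risk at t_i,

    S(t) = prod_{t_i <= t} (1 - d_i / q_i),
    H(t) = sum_{t_i < t} d_i / q_i,
    V(S(t)) = S(t)^2 sum_{t_i < t} d_i / (q_i (q_i - d_i)),

and the 100(1 - a)% interval is S(t) +/- z(a/2) sqrt(V(S(t))), clipped to
[0, 1] on the plain scale. Children censored at an event time are still at
risk at that time (the deaths-before-censorings tie convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import SurvivalDataset

#: DHS standard age segments, [start, end) in months
DHS_SEGMENTS: tuple[tuple[float, float], ...] = (
    (0, 1),
    (1, 3),
    (3, 6),
    (6, 12),
    (12, 24),
    (24, 36),
    (36, 48),
    (48, 60),
)


def _validate(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be nonnegative and finite")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events


@dataclass
class NonparametricEstimate:
    """Event-time table with product-limit and cumulative-hazard columns.

    Arrays are indexed by the k distinct death times; ``survival[i]``,
    ``cum_hazard[i]`` and ``variance[i]`` are the values AT t_i (deaths at
    t_i included). The step-function evaluators follow the printed
    conventions: S uses t_i <= t, H and V use t_i < t.
    """

    event_times: np.ndarray  # distinct death times, ascending
    deaths: np.ndarray  # d_i
    at_risk: np.ndarray  # q_i
    survival: np.ndarray  # S(t_i)
    cum_hazard: np.ndarray  # H(t_i+) = sum_{t_j <= t_i} d_j/q_j
    variance: np.ndarray  # Greenwood V(S(t_i)); inf past a q_i = d_i time
    ci_level: float = 0.95
    n: int = 0
    unbounded_tail_from: float | None = None  # first time with q_i = d_i

    def survival_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """S(t) = prod over t_i <= t."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate(([1.0], self.survival))[idx]
        return float(s) if np.isscalar(t) else s

    def cum_hazard_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """H(t) = sum over t_i < t."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="left")
        h = np.concatenate(([0.0], self.cum_hazard))[idx]
        return float(h) if np.isscalar(t) else h

    def variance_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """V(S(t)) with the sum over t_i < t and S evaluated at t."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t_arr, side="left")
        gsum = np.concatenate(([0.0], self._greenwood_sum))[idx]
        s = self.survival_at(t_arr)
        v = np.asarray(s) ** 2 * gsum
        return float(v) if np.isscalar(t) else v

    @property
    def _greenwood_sum(self) -> np.ndarray:
        """Cumulative sum_{t_j <= t_i} d_j / (q_j (q_j - d_j))."""
        with np.errstate(divide="ignore"):
            terms = np.where(
                self.at_risk > self.deaths,
                self.deaths / (self.at_risk * np.maximum(self.at_risk - self.deaths, 1e-300)),
                np.inf,
            )
        return np.cumsum(terms)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = greenwood_ci(self, 1.0 - self.ci_level)
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
                "survival": self.survival,
                "cum_hazard": self.cum_hazard,
                "variance": self.variance,
                "lower": lo,
                "upper": hi,
            }
        )


def _event_table(times: np.ndarray, events: np.ndarray) -> NonparametricEstimate:
    times, events = _validate(times, events)
    death_times = np.unique(times[events == 1])
    # q_i counts everyone with observed time >= t_i (censored at t_i included)
    order = np.sort(times)
    at_risk = len(times) - np.searchsorted(order, death_times, side="left")
    deaths = np.array([np.sum((times == t) & (events == 1)) for t in death_times])
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > 0, deaths / at_risk, np.nan)
    survival = np.cumprod(1.0 - frac)
    cum_hazard = np.cumsum(frac)
    est = NonparametricEstimate(
        event_times=death_times,
        deaths=deaths,
        at_risk=at_risk,
        survival=survival,
        cum_hazard=cum_hazard,
        variance=np.empty(len(death_times)),
        n=len(times),
    )
    gsum = est._greenwood_sum
    est.variance = survival**2 * gsum
    saturated = np.flatnonzero(deaths == at_risk)
    if saturated.size:
        est.unbounded_tail_from = float(death_times[saturated[0]])
    return est


def kaplan_meier(
    times: np.ndarray, events: np.ndarray, ci_level: float = 0.95
) -> NonparametricEstimate:
    """Product-limit estimate of the survival function.

    Censored observations reduce the risk set at the next death time; with
    no censoring the estimate equals the complement of the empirical CDF.
    """
    if np.any(np.asarray(times, dtype=float) <= 0):
        raise ValueError("times must be positive")
    est = _event_table(np.asarray(times), np.asarray(events))
    est.ci_level = ci_level
    return est


def nelson_aalen(
    times: np.ndarray, events: np.ndarray, ci_level: float = 0.95
) -> NonparametricEstimate:
    """Nelson-Aalen estimate of the cumulative hazard (same event table)."""
    return kaplan_meier(times, events, ci_level=ci_level)


def greenwood_ci(
    est: NonparametricEstimate, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise normal interval S +/- z(alpha/2) sqrt(V), clipped to [0, 1].

    Past a time where every child at risk dies (q_i = d_i) the variance sum
    is undefined; those bounds are returned as [0, 1] and the estimate
    carries ``unbounded_tail_from``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(est.variance)
    with np.errstate(invalid="ignore"):
        lo = np.clip(est.survival - half, 0.0, 1.0)
        hi = np.clip(est.survival + half, 0.0, 1.0)
    bad = ~np.isfinite(est.variance)
    lo[bad], hi[bad] = 0.0, 1.0
    return lo, hi


# ---------------------------------------------------------------------------
# DHS-style component probabilities
# ---------------------------------------------------------------------------


@dataclass
class ComponentProbTable:
    """Segment-wise death probabilities of a synthetic cohort.

    ``component_prob[s]`` is q_s, the probability of dying inside segment s
    given survival to its start; ``cumulative_prob[s]`` chains complements,
    1 - prod_{s' <= s} (1 - q_{s'}). Segments with an empty denominator
    yield NaN.
    """

    segments: tuple[tuple[float, float], ...]
    component_prob: np.ndarray
    cumulative_prob: np.ndarray
    deaths: np.ndarray = field(default_factory=lambda: np.array([]))
    exposure: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_start": [s for s, _ in self.segments],
                "segment_end": [e for _, e in self.segments],
                "deaths": self.deaths,
                "exposure": self.exposure,
                "component_prob": self.component_prob,
                "cumulative_prob": self.cumulative_prob,
            }
        )


def component_probabilities(
    data: SurvivalDataset | tuple[np.ndarray, np.ndarray],
    segments: tuple[tuple[float, float], ...] = DHS_SEGMENTS,
) -> ComponentProbTable:
    """Synthetic-cohort component death probabilities over age segments.

    For each segment [a, b), q_s = deaths in the segment divided by the
    effective number entering it, where a child censored inside the
    segment contributes half a unit of exposure (the standard DHS-manual
    treatment of within-segment censoring, here applied to a synthetic
    cohort). With no censoring this reduces to deaths over survivors
    entering the segment.
    """
    if isinstance(data, SurvivalDataset):
        times, events = data.time, data.event
    else:
        times, events = data
    times, events = _validate(np.asarray(times), np.asarray(events))

    k = len(segments)
    q = np.full(k, np.nan)
    deaths_s = np.zeros(k)
    exposure_s = np.full(k, np.nan)
    for s, (a, b) in enumerate(segments):
        entering = np.sum(times >= a)
        inside = (times >= a) & (times < b)
        d = np.sum(inside & (events == 1))
        c = np.sum(inside & (events == 0))
        denom = entering - 0.5 * c
        deaths_s[s] = d
        if denom > 0:
            exposure_s[s] = denom
            q[s] = d / denom
    with np.errstate(invalid="ignore"):
        cumulative = 1.0 - np.cumprod(1.0 - q)
    return ComponentProbTable(
        segments=tuple(segments),
        component_prob=q,
        cumulative_prob=cumulative,
        deaths=deaths_s,
        exposure=exposure_s,
    )
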