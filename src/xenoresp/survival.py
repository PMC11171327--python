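"""Event-free-survival statistics from first principles.

Kaplan-Meier product-limit estimation, median time to event, and the
two-group log-rank test are implemented directly from their definitions
(they are the analysis contract here, not a convenience), with the
standard tie convention that censorings at an event time occur after the
events at that time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from xenoresp.trajectory import EventResult

#: Smallest p-value reported numerically; smaller tails are floored and
#: flagged so a p of literal zero is never printed.
P_FLOOR = 1e-16


@dataclass
class SurvivalCurve:
    """Product-limit estimate of the event-free-survival function."""

    event_times: np.ndarray    # distinct times with >=1 event, sorted
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # risk-set size at each event time
    events: np.ndarray         # events at each event time
    median_efs: float          # np.inf encodes "not reached"

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median_efs)


@dataclass
class LogRankResult:
    statistic: float           # chi-square, 1 df
    p_value: float
    p_is_floor: bool = False   # True when the true tail is below P_FLOOR


def _to_arrays(events: list[EventResult]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([e.time_days for e in events], dtype=float)
    d = np.array([e.observed for e in events], dtype=bool)
    return t, d


def km_fit(events: list[EventResult]) -> SurvivalCurve:
    """Kaplan-Meier estimator.

    At each distinct event time t_j with d_j events out of n_j at risk,
    S multiplies by (1 - d_j / n_j).  Censored records leave the risk set
    at their censoring time without contributing a factor.  The median is
    the smallest time at which S(t) <= 0.5, or "not reached" (inf).
    """
    if not events:
        raise ValueError("km_fit requires at least one record")
    times, observed = _to_arrays(events)

    event_times = np.unique(times[observed])
    surv = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    n_events = np.empty(len(event_times), dtype=int)
    s = 1.0
    for j, t in enumerate(event_times):
        n_j = int(np.sum(times >= t))  # censorings at t stay at risk for events at t
        d_j = int(np.sum(observed & (times == t)))
        s *= 1.0 - d_j / n_j
        surv[j], at_risk[j], n_events[j] = s, n_j, d_j

    below = np.nonzero(surv <= 0.5)[0]
    median = float(event_times[below[0]]) if len(below) else np.inf
    return SurvivalCurve(event_times=event_times, survival=surv,
                         at_risk=at_risk, events=n_events, median_efs=median)


def median_time_to_event(curve: SurvivalCurve) -> float:
    """Median EFS of a fitted curve; ``inf`` means not reached."""
    return curve.median_efs


def logrank(group_a: list[EventResult], group_b: list[EventResult]) -> LogRankResult:
    """Two-sided two-sample log-rank test.

    Sums observed-minus-expected events in group A over the distinct event
    times of the pooled sample, with the hypergeometric variance at each
    time; the squared standardized sum is referred to chi-square(1).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must contain at least one record")
    ta, da = _to_arrays(group_a)
    tb, db = _to_arrays(group_b)
    times = np.concatenate([ta, tb])
    observed = np.concatenate([da, db])
    in_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[observed]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int((observed & (times == t)).sum())
        d_a = int((observed & (times == t) & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)

    if var == 0.0:
        return LogRankResult(statistic=0.0, p_value=1.0)
    chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    if p < P_FLOOR:
        return LogRankResult(statistic=float(chi2), p_value=P_FLOOR, p_is_floor=True)
    return LogRankResult(statistic=float(chi2), p_value=p)
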