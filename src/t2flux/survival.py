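"""Time-to-endpoint analysis for treatment-group comparisons.

Survival time runs from tumor cell injection to the humane endpoint; animals
euthanized symptom-free at the end of observation are right-censored.  Groups
are summarized by the Kaplan-Meier product-limit estimator with the median
defined as the first time the estimated survival fraction falls to <= 0.5,
compared by the two-group log-rank test, and their survival times compared
by the two-sided Mann-Whitney U test (exact by enumeration for small
samples).  Treatment effect on medians is reported as percent enhancement
over the control median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "LogrankResult",
    "km_curve",
    "logrank",
    "mann_whitney",
    "percent_enhancement",
]

#: Combined sample size up to which the Mann-Whitney p is exact by enumeration.
EXACT_ENUMERATION_LIMIT = 20


@dataclass
class GroupSummary:
    """Kaplan-Meier summary of one group.

    ``times``/``survival`` give the right-continuous step function S(t)
    evaluated after each distinct event time (S starts at 1 before the first
    event).  ``median_days`` is the first time with S <= 0.5, NaN when the
    curve never reaches 0.5 (``median_defined`` False).
    ``event_time_median_days`` is the plain sample median of uncensored
    event times, emitted as a secondary summary.
    """

    group: str
    times: np.ndarray
    survival: np.ndarray
    median_days: float
    median_defined: bool
    n: int
    n_events: int
    event_time_median_days: float = math.nan

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


class LogrankResult(NamedTuple):
    chi_square: float
    p: float
    defined: bool
    message: str


class MannWhitneyResult(NamedTuple):
    u: float
    p: float
    method: str


def km_curve(times: Sequence[float], events: Sequence[bool], group: str = "") -> GroupSummary:
    """Product-limit survival estimate with right-censoring.

    At each distinct event time t with d events among n at risk, S is
    multiplied by (1 - d/n).  Censored times leave the curve unchanged but
    shrink the risk set.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0 or t.shape != e.shape:
        raise ValueError("need at least one record with matching event flags")
    if np.any(t < 0):
        raise ValueError("survival times must be non-negative")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])

    surv = []
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & e))
        s *= 1.0 - d / n_risk
        surv.append(s)
    survival = np.asarray(surv)

    median = math.nan
    defined = False
    for et, s_after in zip(event_times, survival):
        if s_after <= 0.5:
            median, defined = float(et), True
            break

    n_events = int(e.sum())
    sample_median = float(np.median(t[e])) if n_events else math.nan
    return GroupSummary(
        group=group,
        times=event_times,
        survival=survival,
        median_days=median,
        median_defined=defined,
        n=int(t.size),
        n_events=n_events,
        event_time_median_days=sample_median,
    )


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> LogrankResult:
    """Two-group log-rank test (1 df, two-sided).

    At each distinct event time the observed group-A events are compared
    with their hypergeometric expectation given the pooled risk sets.  A
    group with zero events makes the test degenerate: an undefined-flag
    result with a message is returned instead of a statistic.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups need at least one record")
    for name, ev in (("A", ea), ("B", eb)):
        if not ev.any():
            return LogrankResult(
                math.nan, math.nan, False, f"group {name} has zero events; log-rank undefined"
            )

    pooled_t = np.concatenate([ta, tb])
    pooled_e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(pooled_t[pooled_e])

    observed_a = expected_a = variance = 0.0
    for et in event_times:
        at_risk = pooled_t >= et
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (pooled_t == et) & pooled_e
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        observed_a += d_a
        expected_a += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)

    if variance == 0.0:
        return LogrankResult(0.0, 1.0, True, "no variance in risk sets")
    chi2 = (observed_a - expected_a) ** 2 / variance
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), p, True, "")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a: #{a > b} pairs, ties counted half."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(times_a: Sequence[float], times_b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test on survival times (censoring ignored).

    For combined n <= 20 the p value is exact: every assignment of the
    pooled values to group A is enumerated (ties handled by midranks), and
    p is the probability of a U at least as far from its null mean
    n_a*n_b/2 as observed.  Larger samples use the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    u_obs = _u_statistic(a, b)
    center = na * nb / 2.0

    if na + nb <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)  # midranks; U = ranksum_A - na(na+1)/2
        offset = na * (na + 1) / 2.0
        dev_obs = abs(u_obs - center)
        hits = total = 0
        for subset in combinations(range(na + nb), na):
            u = ranks[list(subset)].sum() - offset
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                hits += 1
        return MannWhitneyResult(u_obs, hits / total, "exact")

    n = na + nb
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u_obs, 1.0, "asymptotic")
    z = (abs(u_obs - center) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, float(2.0 * stats.norm.sf(max(z, 0.0))))
    return MannWhitneyResult(u_obs, p, "asymptotic")


def percent_enhancement(median_treated_days: float, median_control_days: float) -> float:
    """Percent change of the treated median over the control median.

    Rounded to the nearest integer, halves away from zero.  An undefined
    (NaN) median propagates as NaN.
    """
    if math.isnan(median_treated_days) or math.isnan(median_control_days):
        return math.nan
    if median_treated_days <= 0 or median_control_days <= 0:
        raise ValueError("medians must be positive")
    pct = 100.0 * (median_treated_days - median_control_days) / median_control_days
    return float(math.floor(pct + 0.5) if pct >= 0 else math.ceil(pct - 0.5))
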