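"""Kaplan-Meier estimation and weighted log-rank tests, from first principles.

Implements the product-limit survival estimator, the k-sample log-rank
(Mantel-Cox) chi-square test, its Gehan-Breslow-Wilcoxon variant (weights
each event time by the total number at risk, emphasising early events),
the 1-df log-rank test for trend across ordered groups, and at-risk
tables at fixed intervals. Ties follow the standard convention that
events precede censoring at the same time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

WEIGHTINGS = ("mantel_cox", "gehan_breslow_wilcoxon")


@dataclass
class KMCurve:
    """Product-limit survival curve."""

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray  # S(t) immediately after each event time
    n_at_risk: np.ndarray  # number at risk just before each event time
    n_events: np.ndarray  # events at each event time
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous."""
        if len(self.event_times) == 0 or t < self.event_times[0]:
            return 1.0
        i = np.searchsorted(self.event_times, t, side="right") - 1
        return float(self.survival[i])


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float


def _clean(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events, dtype=int).ravel()
    if t.size == 0:
        raise ValueError("empty survival data")
    if t.size != e.size:
        raise ValueError("times and events lengths differ")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("events must be 0 (censored) or 1 (event)")
    return t, e


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t, e = _clean(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    distinct = np.unique(t[e == 1])
    n = t.size
    surv, at_risk, d_out = [], [], []
    s = 1.0
    for ti in distinct:
        ni = int(np.sum(t >= ti))  # censoring at ti still counts as at risk
        di = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - di / ni
        surv.append(s)
        at_risk.append(ni)
        d_out.append(di)
    return KMCurve(
        event_times=distinct,
        survival=np.array(surv),
        n_at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(d_out, dtype=int),
        censor_times=np.sort(t[e == 0]),
    )


def _logrank_moments(groups):
    """Per-event-time observed-minus-expected vectors and covariances.

    Returns (times, O-E matrix [times x groups], covariance stack
    [times x groups x groups], total at risk per time).
    """
    cleaned = [_clean(t, e) for t, e in groups]
    k = len(cleaned)
    if k < 2:
        raise ValueError("need at least two groups")
    all_t = np.concatenate([t for t, _ in cleaned])
    all_e = np.concatenate([e for _, e in cleaned])
    if all_e.sum() == 0:
        raise ValueError("no events in any group; test undefined")
    times = np.unique(all_t[all_e == 1])
    m = len(times)
    omine = np.zeros((m, k))
    cov = np.zeros((m, k, k))
    totals = np.zeros(m)
    for idx, ti in enumerate(times):
        nj = np.array([np.sum(t >= ti) for t, _ in cleaned], dtype=float)
        dj = np.array(
            [np.sum((t == ti) & (e == 1)) for t, e in cleaned], dtype=float
        )
        n = nj.sum()
        d = dj.sum()
        totals[idx] = n
        if n <= 0 or d <= 0:
            continue
        expected = d * nj / n
        omine[idx] = dj - expected
        if n > 1:
            frac = nj / n
            hyper = d * (n - d) / (n - 1)
            cov[idx] = hyper * (np.diag(frac) - np.outer(frac, frac))
    return times, omine, cov, totals


def logrank(groups, weights: str = "mantel_cox") -> TestResult:
    """k-sample weighted log-rank chi-square test on (k-1) df.

    ``groups`` is a list of (times, events) pairs. Mantel-Cox uses unit
    weights; Gehan-Breslow-Wilcoxon weights each event time by the total
    number at risk there.
    """
    if weights not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weights!r}")
    _, omine, cov, totals = _logrank_moments(groups)
    w = np.ones_like(totals) if weights == "mantel_cox" else totals
    u = (w[:, None] * omine).sum(axis=0)
    v = (w[:, None, None] ** 2 * cov).sum(axis=0)
    k = omine.shape[1]
    # drop the last group: the O-E vector sums to zero
    u_r = u[: k - 1]
    v_r = v[: k - 1, : k - 1]
    stat = float(u_r @ np.linalg.pinv(v_r) @ u_r)
    stat = max(stat, 0.0)
    df = k - 1
    return TestResult(statistic=stat, df=df, p=float(chi2.sf(stat, df)))


def logrank_trend(groups, scores=None) -> TestResult:
    """1-df log-rank test for trend across ordered groups.

    statistic = (sum_j s_j (O_j - E_j))^2 / (s' V s) with equally spaced
    integer scores by default. Requires at least 3 groups (with 2 the
    trend test is the ordinary log-rank test).
    """
    k = len(groups)
    if k < 3:
        raise ValueError("trend test needs at least 3 ordered groups")
    s = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(scores, float)
    if s.size != k:
        raise ValueError("one score per group required")
    _, omine, cov, _ = _logrank_moments(groups)
    u = float(s @ omine.sum(axis=0))
    var = float(s @ cov.sum(axis=0) @ s)
    if var <= 0:
        return TestResult(statistic=0.0, df=1, p=1.0)
    stat = u * u / var
    return TestResult(statistic=stat, df=1, p=float(chi2.sf(stat, 1)))


def at_risk_table(groups, interval: float = 2.0, horizon: float = 10.0) -> np.ndarray:
    """Number still at risk (time >= t) per group at 0, interval, ..., horizon."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    ticks = np.arange(0.0, horizon + 1e-9, interval)
    table = np.empty((len(groups), len(ticks)), dtype=int)
    for g, (times, events) in enumerate(groups):
        t, _ = _clean(times, events)
        table[g] = [(t >= tick).sum() for tick in ticks]
    return table


def records_to_survival(records, event_outcome: str = "died_of_disease"):
    """(times, events) arrays from clinical records.

    Overall-survival convention for the re-analysis: only the stated
    event outcome counts as an event; other-cause deaths, censoring and
    unknown outcomes are treated as censored at their follow-up time.
    """
    times = np.array([r.survival_time for r in records], dtype=float)
    events = np.array([int(r.outcome == event_outcome) for r in records], dtype=int)
    return times, events
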