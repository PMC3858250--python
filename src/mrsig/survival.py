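"""Nonparametric survival estimation and comparison.

Kaplan-Meier product-limit curves, the log-rank test for two or more
groups, and Harrell's concordance index.  These are deliberately small,
direct implementations whose conventions are spelled out per function; the
test suite cross-checks them against an independent survival library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .containers import SurvivalOutcome, outcomes_to_arrays

__all__ = [
    "KMCurve",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "concordance_index",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S changes only at event times, S(0) = 1."""

    event_times: np.ndarray      # ordered distinct times with >= 1 event
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray         # S(t) just after each event time
    max_follow_up: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival curve must be non-increasing")


def km_estimate(outcomes: Iterable[SurvivalOutcome]) -> KMCurve:
    """Kaplan-Meier estimator.

    Censoring tied with an event time is processed after the events at that
    time (the censored subject counts as at risk there).  All-censored input
    yields a flat S = 1 curve.
    """
    _, time, event, _ = outcomes_to_arrays(outcomes)
    if len(time) == 0:
        raise ValueError("no outcomes given")
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    ev_times = np.unique(t[d == 1])
    at_risk = len(t) - np.searchsorted(t, ev_times, side="left")
    events = np.array([int(d[t == u].sum()) for u in ev_times])
    surv = np.cumprod(1.0 - events / at_risk) if len(ev_times) else np.array([])
    return KMCurve(
        event_times=ev_times,
        at_risk=at_risk.astype(int),
        events=events,
        survival=surv,
        max_follow_up=float(t[-1]),
    )


def survival_at(curve: KMCurve, t: float) -> tuple[float, bool]:
    """Right-continuous step evaluation S(t); returns (probability, extrapolated).

    ``extrapolated`` flags queries beyond the last observed follow-up, where
    the last value is carried forward.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    extrapolated = t > curve.max_follow_up
    if len(curve.event_times) == 0:
        return 1.0, extrapolated
    idx = np.searchsorted(curve.event_times, t, side="right")
    return (1.0 if idx == 0 else float(curve.survival[idx - 1])), extrapolated


def logrank_test(
    groups: Sequence[Iterable[SurvivalOutcome]],
) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups; returns (chi2, df, p).

    Observed-minus-expected event counts over the pooled risk sets, with the
    hypergeometric variance (including the tie correction factor
    (n - d)/(n - 1)); chi-square on (groups - 1) degrees of freedom.
    """
    groups = [list(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("log-rank test requires at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("log-rank test requires non-empty groups")
    parts = [outcomes_to_arrays(g) for g in groups]
    times = [p[1] for p in parts]
    events = [p[2] for p in parts]
    if sum(int(e.sum()) for e in events) == 0:
        raise ValueError("log-rank test requires at least one event")
    G = len(groups)
    pooled = np.unique(np.concatenate([t[e == 1] for t, e in zip(times, events)]))
    OmE = np.zeros(G)
    V = np.zeros((G, G))
    for u in pooled:
        n_g = np.array([np.sum(t >= u) for t in times], dtype=float)
        d_g = np.array(
            [np.sum((t == u) & (e == 1)) for t, e in zip(times, events)], dtype=float
        )
        n, d = n_g.sum(), d_g.sum()
        if n <= 0 or d <= 0:
            continue
        OmE += d_g - d * n_g / n
        if n > 1:
            frac = n_g / n
            V += (
                d
                * (n - d)
                / (n - 1)
                * (np.diagflat(frac) - np.outer(frac, frac))
            )
    df = G - 1
    sub_V = V[:df, :df]
    sub_O = OmE[:df]
    try:
        chi2 = float(sub_O @ np.linalg.solve(sub_V, sub_O))
    except np.linalg.LinAlgError:
        chi2 = float(sub_O @ np.linalg.pinv(sub_V) @ sub_O)
    chi2 = max(chi2, 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def concordance_index(
    scores: Sequence[float], outcomes: Iterable[SurvivalOutcome]
) -> float:
    """Harrell's c for a higher-score-means-higher-risk predictor.

    Permissible pairs: the subject with the shorter follow-up had the event
    (pairs tied on time with both events are excluded; a tied-time
    event/censored pair counts, the event subject failing first).  Score
    ties within a permissible pair contribute 0.5.
    """
    _, time, event, _ = outcomes_to_arrays(outcomes)
    s = np.asarray(scores, dtype=float)
    if s.shape != time.shape:
        raise ValueError("scores and outcomes are not aligned")
    # pair (i, j) permissible with i failing first
    ti, tj = time[:, None], time[None, :]
    di = event[:, None].astype(bool)
    dj = event[None, :].astype(bool)
    permissible = di & ((ti < tj) | ((ti == tj) & ~dj))
    n_perm = int(permissible.sum())
    if n_perm == 0:
        raise ValueError("no permissible pairs (need an event with a longer-lived partner)")
    si, sj = s[:, None], s[None, :]
    concordant = permissible & (si > sj)
    tied = permissible & (si == sj)
    return float((concordant.sum() + 0.5 * tied.sum()) / n_perm)
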