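"""Event-specific coupling between behavior and neural subset series.

Whole-recording correlations can be driven by coarse on/off structure; the
event-specific analysis instead correlates each subset series with the
behavior *within each behavioral event window* and calibrates the resulting
short-series correlations against cyclically time-shifted controls.  A
subset counts as "strongly correlated" with an event when its real
correlation exceeds the 99.9th-percentile order statistic of the event's
control correlations; with 1000 controls the chance expectation of the
strong count is 1, and an event is called significant when the count
exceeds 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .events import EventSet
from .preprocess import TimeSeries

__all__ = ["EventLinkResult", "event_specific_correlations", "active_time_fraction"]


@dataclass(frozen=True)
class EventLinkResult:
    """Counts from the event-specific correlation analysis.

    Per behavioral event: the number of strongly correlated subsets and a
    significance flag (strong count > ``sig_count``).  Per subset: the
    number of events for which it was strong.  ``evaluated`` marks events
    long enough (>= 3 samples) to have been scored.
    """

    n_strong_subsets: np.ndarray
    significant: np.ndarray
    n_strong_events: np.ndarray
    evaluated: np.ndarray
    n_controls: int
    sig_count: int


def _window_corr(beh: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``beh`` (length L) with each row of ``mat``."""
    b = beh - beh.mean()
    m = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((b @ b) * np.einsum("ij,ij->i", m, m))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, m @ b / np.where(denom == 0, 1.0, denom), 0.0)
    return np.clip(r, -1.0, 1.0)


def event_specific_correlations(
    behavior: TimeSeries,
    beh_events: EventSet,
    subset_series: list[TimeSeries],
    n_controls: int = 1000,
    rng_seed=None,
    sig_count: int = 4,
    strong_quantile: float = 0.999,
) -> EventLinkResult:
    """Score every (behavioral event, neural subset) pair against shift nulls.

    For each event window the real correlation of the behavior with each
    subset is compared with ``n_controls`` control correlations, each
    obtained from an independently cyclically shifted copy of a subset
    series over the same window (controls are drawn per event, cycling over
    subsets, so each event gets its own null distribution).  Events shorter
    than 3 samples are skipped with a warning.

    Raises
    ------
    ValueError
        If ``n_controls`` < 100.
    """
    if n_controls < 100:
        raise ValueError("n_controls must be >= 100 for a stable null")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n_sub = len(subset_series)
    if n_sub == 0:
        raise ValueError("need at least one subset series")
    sub = np.stack([ts.values for ts in subset_series])
    t = sub.shape[1]
    beh = behavior.values
    if beh.size != t:
        raise ValueError("behavior and subset series must share the time axis")

    n_ev = len(beh_events)
    n_strong = np.zeros(n_ev, dtype=int)
    evaluated = np.zeros(n_ev, dtype=bool)
    strong_by_subset = np.zeros(n_sub, dtype=int)
    # which order statistic of the controls the real r must (strictly) exceed
    k_stat = int(np.ceil(strong_quantile * n_controls)) - 1
    ctrl_subsets = np.arange(n_controls) % n_sub

    skipped = 0
    for e in range(n_ev):
        w = np.arange(beh_events.start[e], beh_events.end[e])
        if w.size < 3:
            skipped += 1
            continue
        evaluated[e] = True
        real = _window_corr(beh[w], sub[:, w])
        # shifts start at 1: a zero shift would reproduce the real window
        # and is no control at all
        shifts = rng.integers(1, t, size=n_controls)
        idx = (w[None, :] - shifts[:, None]) % t
        ctrl_mat = sub[ctrl_subsets[:, None], idx]
        ctrl = _window_corr(beh[w], ctrl_mat)
        thr = np.sort(ctrl)[k_stat]
        strong = real > thr
        n_strong[e] = int(strong.sum())
        strong_by_subset += strong
    if skipped:
        warnings.warn(f"skipped {skipped} behavioral event(s) shorter than 3 samples")

    return EventLinkResult(
        n_strong_subsets=n_strong,
        significant=evaluated & (n_strong > sig_count),
        n_strong_events=strong_by_subset,
        evaluated=evaluated,
        n_controls=n_controls,
        sig_count=sig_count,
    )


def active_time_fraction(beh_events: EventSet, link: EventLinkResult) -> float:
    """Fraction of behaviorally-active time inside significant events.

    (Sum of durations of significant events) / (sum of durations of all
    events).

    Raises
    ------
    ValueError
        If the event set is empty or does not match the link result.
    """
    if len(beh_events) == 0:
        raise ValueError("empty event set")
    if len(beh_events) != link.significant.size:
        raise ValueError("link result was computed on a different event set")
    total = beh_events.durations.sum()
    return float(beh_events.durations[link.significant].sum() / total)
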