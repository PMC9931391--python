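"""Duration exponents and crackling-noise scaling relations.

For events whose sizes lie in the power-law range [s_min, s_max] of the size
distribution, three exponents are estimated: tau (sizes, from the range
fitter), alpha (durations, truncated MLE over the duration span of the same
events), and beta (slope of log10 size vs log10 duration, ordinary least
squares).  Crackling-noise theory predicts beta = (alpha - 1) / (tau - 1) at
criticality; comparing the fitted beta with this prediction tests that
theory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import EventSet
from .powerlaw import (
    PowerLawFit,
    TAU_GRID,
    goodness_of_fit,
    truncated_mle_exponent,
)

__all__ = [
    "ScalingResult",
    "duration_exponent",
    "size_vs_duration",
    "crackling_prediction",
    "compute_scaling",
]


@dataclass(frozen=True)
class ScalingResult:
    """Exponent triple for one event population.

    ``beta_crackling`` is NaN when tau is too close to 1 for the prediction
    (alpha - 1)/(tau - 1) to be defined.
    """

    tau: float
    alpha: float
    beta_fit: float
    beta_crackling: float
    n_events: int
    alpha_F: float


def _in_range(events: EventSet, size_fit: PowerLawFit) -> EventSet:
    if not size_fit.ok:
        raise ValueError("size fit has no power-law range (r = 0)")
    mask = (events.sizes >= size_fit.s_min) & (events.sizes <= size_fit.s_max)
    return events.select(mask)


def duration_exponent(
    events: EventSet,
    size_fit: PowerLawFit,
    F_criterion: float = 0.80,
    rng_seed=None,
    n_surrogate: int = 500,
    grid: np.ndarray = TAU_GRID,
) -> tuple[float, float]:
    """Truncated-MLE exponent alpha of the durations of in-range events.

    Durations of the events whose *sizes* fall inside the size power-law
    range are fit with the same truncated-MLE machinery; the truncation
    bounds are the min and max of those durations.  Returns ``(alpha, F)``
    where F is the surrogate goodness-of-fit of the duration fit itself.

    Raises
    ------
    ValueError
        If the size fit has r = 0 or the filtered durations are degenerate.
    """
    sel = _in_range(events, size_fit)
    durs = sel.durations
    if durs.size < 10:
        raise ValueError(f"only {durs.size} in-range events; need >= 10")
    d_min, d_max = float(durs.min()), float(durs.max())
    if d_min >= d_max:
        raise ValueError("all in-range events share one duration; alpha undefined")
    alpha, _ = truncated_mle_exponent(durs, d_min, d_max, grid)
    dur_fit = PowerLawFit(
        tau=alpha, s_min=d_min, s_max=d_max,
        range_decades=float(np.log10(d_max / d_min)),
        F=0.0, n_tail=durs.size,
    )
    F = goodness_of_fit(durs, dur_fit, n_surrogate=n_surrogate, rng_seed=rng_seed)
    return alpha, F


def size_vs_duration(
    events: EventSet,
    size_fit: PowerLawFit | None = None,
    in_range_only: bool = True,
) -> float:
    """Slope beta of the ordinary least-squares fit of log10(S) on log10(T).

    By default only events inside the size power-law range are used (so tau,
    alpha and beta describe the same event population); pass
    ``in_range_only=False`` to regress over all events.

    Raises
    ------
    ValueError
        If fewer than 10 events remain or all durations are equal.
    """
    sel = _in_range(events, size_fit) if (in_range_only and size_fit is not None) else events
    if len(sel) < 10:
        raise ValueError(f"need >= 10 events for the size-duration regression, got {len(sel)}")
    log_t = np.log10(sel.durations)
    log_s = np.log10(sel.sizes)
    if np.ptp(log_t) == 0:
        raise ValueError("zero variance in durations; slope undefined")
    return float(stats.linregress(log_t, log_s).slope)


def crackling_prediction(tau: float, alpha: float) -> float:
    """Crackling-noise prediction beta = (alpha - 1) / (tau - 1).

    Raises
    ------
    ValueError
        If |tau - 1| <= 1e-6: the prediction is undefined when the size
        exponent sits at 1.
    """
    if abs(tau - 1.0) <= 1e-6:
        raise ValueError("tau is too close to 1; crackling prediction undefined")
    return (alpha - 1.0) / (tau - 1.0)


def compute_scaling(
    events: EventSet,
    size_fit: PowerLawFit,
    F_criterion: float = 0.80,
    rng_seed=None,
    n_surrogate: int = 500,
) -> ScalingResult:
    """Full exponent triple (tau, alpha, beta) for one event population."""
    alpha, alpha_F = duration_exponent(
        events, size_fit, F_criterion, rng_seed=rng_seed, n_surrogate=n_surrogate
    )
    beta = size_vs_duration(events, size_fit)
    try:
        beta_c = crackling_prediction(size_fit.tau, alpha)
    except ValueError:
        beta_c = float("nan")
    n = int(np.count_nonzero((events.sizes >= size_fit.s_min) & (events.sizes <= size_fit.s_max)))
    return ScalingResult(
        tau=size_fit.tau, alpha=alpha, beta_fit=beta,
        beta_crackling=beta_c, n_events=n, alpha_F=alpha_F,
    )
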