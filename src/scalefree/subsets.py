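"""Shotgun discovery of correlated neural subsets.

A *subset* is built around a seed neuron: the k neurons most correlated with
the seed ("correlated" mode), or the k/2 most correlated plus the k/2 most
anticorrelated ("canceling" mode).  The subset time series is the mean of
the member z-scored traces; its suprathreshold events are then scored with
the power-law range fitter.  Repeating over many random seeds and over a
time-shifted surrogate of the activity matrix separates genuine scale-free
subsets from chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .events import extract_events
from .powerlaw import PowerLawFit, fit_power_law_range
from .preprocess import TimeSeries

__all__ = [
    "SubsetResult",
    "correlation_spectrum",
    "build_subset",
    "time_shift_surrogate",
    "shotgun_search",
]


@dataclass(frozen=True)
class SubsetResult:
    """One seed's subset: members, mean series, power-law fit, behavior link."""

    seed_id: int
    member_ids: np.ndarray
    subset_series: TimeSeries
    fit: PowerLawFit | None
    behavior_corr: dict[str, float]


def _zscore_rows(activity: np.ndarray) -> np.ndarray:
    """Row-wise z-scored copy; constant rows become zero with a warning."""
    activity = np.asarray(activity, dtype=float)
    mean = activity.mean(axis=1, keepdims=True)
    sd = activity.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant neuron trace(s); correlations set to 0")
        sd = np.where(sd == 0, 1.0, sd)
    z = (activity - mean) / sd
    z[flat] = 0.0
    return z


def correlation_spectrum(activity: np.ndarray, seed_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of every other neuron with the seed, ranked.

    Returns ``(neuron_ids, r)`` sorted by descending correlation, ties
    broken by ascending neuron index.  Constant traces get r = 0 (with a
    warning from the z-scoring step).
    """
    z = _zscore_rows(activity)
    n_neurons, t = z.shape
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    r = z @ z[seed_id] / t
    others = np.array([i for i in range(n_neurons) if i != seed_id])
    # stable sort on index then descending r -> ties break by neuron index
    order = others[np.argsort(-r[others], kind="stable")]
    return order, r[order]


def build_subset(
    activity: np.ndarray,
    seed_id: int,
    k: int = 50,
    mode: str = "correlated",
    dt: float = 1.0,
    include_seed: bool = False,
) -> SubsetResult:
    """Assemble the subset around one seed and average its z-scored traces.

    ``mode="correlated"`` takes the top-k of the correlation spectrum (seed
    excluded unless ``include_seed``); ``mode="canceling"`` takes the k/2
    most correlated plus the k/2 most anticorrelated neurons, whose
    fluctuations largely cancel in the mean.
    """
    n_neurons = activity.shape[0]
    if k >= n_neurons:
        raise ValueError("k must be smaller than the number of neurons")
    order, _ = correlation_spectrum(activity, seed_id)
    if mode == "correlated":
        members = order[:k] if not include_seed else np.concatenate(([seed_id], order[: k - 1]))
    elif mode == "canceling":
        if k % 2:
            raise ValueError("canceling mode requires even k")
        members = np.concatenate([order[: k // 2], order[-(k // 2):]])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    z = _zscore_rows(activity)
    series = TimeSeries(z[members].mean(axis=0), dt=dt, label=f"subset_seed{seed_id}")
    return SubsetResult(
        seed_id=int(seed_id),
        member_ids=np.asarray(members, dtype=int),
        subset_series=series,
        fit=None,
        behavior_corr={},
    )


def time_shift_surrogate(activity: np.ndarray, rng_seed=None) -> np.ndarray:
    """Independently cyclically rotate each neuron's trace.

    A shift of +N moves sample i to position i+N (mod T), so single-neuron
    statistics are preserved exactly while cross-neuron timing is destroyed.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    activity = np.asarray(activity, dtype=float)
    t = activity.shape[1]
    shifts = rng.integers(0, t, size=activity.shape[0])
    out = np.empty_like(activity)
    for i, (row, s) in enumerate(zip(activity, shifts)):
        out[i] = np.roll(row, s)
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def _score_subset(
    sub: SubsetResult,
    behaviors: dict[str, TimeSeries] | None,
    fit_kwargs: dict,
    rng: np.random.Generator,
) -> SubsetResult:
    ev = extract_events(sub.subset_series, threshold="median")
    fit = fit_power_law_range(ev.sizes, rng_seed=rng, **fit_kwargs)
    corr = {}
    if behaviors:
        for label, beh in behaviors.items():
            corr[label] = _pearson(sub.subset_series.values, beh.values)
    return SubsetResult(sub.seed_id, sub.member_ids, sub.subset_series, fit, corr)


def shotgun_search(
    activity: np.ndarray,
    behaviors: dict[str, TimeSeries] | None = None,
    n_seeds: int = 1000,
    k: int = 50,
    rng_seed=None,
    dt: float = 1.0,
    mode: str = "correlated",
    include_seed: bool = False,
    with_surrogate: bool = True,
    **fit_kwargs,
) -> tuple[list[SubsetResult], list[SubsetResult]]:
    """Subset search over random seeds, with a matched time-shifted control.

    Seeds are drawn uniformly without replacement.  For each seed the
    pipeline is: build the subset, extract median-threshold events from its
    mean series, fit the power-law range, and correlate the subset series
    with each behavior.  The identical pipeline runs on one time-shifted
    surrogate of the activity matrix (the same seeds are reused there), so
    every real subset has a chance-level counterpart.

    Extra keyword arguments (``F_criterion``, ``n_surrogate``, ...) are
    forwarded to :func:`scalefree.powerlaw.fit_power_law_range`.

    Returns
    -------
    (results, surrogate_results)
        ``surrogate_results`` is empty when ``with_surrogate=False``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    activity = np.asarray(activity, dtype=float)
    n_neurons = activity.shape[0]
    if n_seeds > n_neurons:
        raise ValueError("n_seeds cannot exceed the number of neurons")
    seeds = rng.choice(n_neurons, size=n_seeds, replace=False)

    results = [
        _score_subset(
            build_subset(activity, s, k=k, mode=mode, dt=dt, include_seed=include_seed),
            behaviors, fit_kwargs, rng,
        )
        for s in seeds
    ]
    surrogate_results: list[SubsetResult] = []
    if with_surrogate:
        shifted = time_shift_surrogate(activity, rng)
        surrogate_results = [
            _score_subset(
                build_subset(shifted, s, k=k, mode=mode, dt=dt, include_seed=include_seed),
                behaviors, fit_kwargs, rng,
            )
            for s in seeds
        ]
    return results, surrogate_results
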