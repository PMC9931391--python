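"""Ground-truth generators for every stage of the analysis pipeline.

The generators emulate the statistical structure the analysis assumes in
real recordings: bursty series whose suprathreshold excursion areas follow
a prescribed truncated power law, and a neural population containing two
mutually anticorrelated groups driven by scale-free latent signals plus
uncorrelated noise neurons, arranged so that the group fluctuations cancel
in the whole-population average.  All generators are bit-reproducible under
fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .powerlaw import sample_truncated_powerlaw
from .preprocess import TimeSeries

__all__ = [
    "PlantedPopulation",
    "sample_truncated_powerlaw",
    "make_event_series",
    "make_planted_population",
]


@dataclass(frozen=True)
class PlantedPopulation:
    """Synthetic population with planted anticorrelated scale-free groups.

    ``activity`` is neurons x time; ``membership`` labels each neuron
    "groupA", "groupB" or "noise"; ``latent`` holds the two anticorrelated
    scale-free drivers; ``behaviors`` maps labels to behavior channels that
    share event times with the group-A driver; ``truth`` records the
    generator parameters.
    """

    activity: np.ndarray
    membership: np.ndarray
    latent: tuple[TimeSeries, TimeSeries]
    behaviors: dict[str, TimeSeries]
    truth: dict


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _bump_profile(size: float, dt: float, shape: str) -> np.ndarray:
    """Sample profile with rectangle-rule area (dt * sum) exactly ``size``."""
    n_samp = max(2, int(round(np.sqrt(size / dt))))
    if shape == "half-sine":
        raw = np.sin(np.pi * (np.arange(n_samp) + 0.5) / n_samp)
    elif shape == "square":
        raw = np.ones(n_samp)
    else:
        raise ValueError(f"unknown event shape {shape!r}")
    return raw * (size / (dt * raw.sum()))


def _default_gap(rng: np.random.Generator, length: int) -> int:
    # expected gap ~ 1.5x the bump length keeps the series at baseline
    # for well over half of the samples
    return length + 1 + int(rng.integers(0, length + 2))


def make_event_series(
    event_sizes: np.ndarray,
    dt: float = 1.0,
    event_shape: str = "half-sine",
    gap_law=None,
    rng_seed=None,
) -> TimeSeries:
    """Series of baseline 0 whose suprathreshold events have given sizes.

    Events are placed sequentially, separated by positive gaps drawn from
    ``gap_law(rng, bump_length)`` (default: roughly 1.5x the bump length).
    Each event is a bump (half-sine by default) whose duration grows as the
    square root of its size and whose rectangle-rule area above baseline
    equals the prescribed size exactly.  Because at least half of the
    samples sit at baseline, the series median is the baseline and
    median-threshold event extraction recovers the prescribed sizes.

    Raises
    ------
    ValueError
        If any size is non-positive, or the drawn gaps leave fewer than
        half of the samples at baseline (median off baseline).
    """
    rng = _as_rng(rng_seed)
    sizes = np.asarray(event_sizes, dtype=float)
    if sizes.size and sizes.min() <= 0:
        raise ValueError("event sizes must be positive")
    if gap_law is None:
        gap_law = _default_gap

    chunks: list[np.ndarray] = []
    for s in sizes:
        bump = _bump_profile(s, dt, event_shape)
        gap = int(gap_law(rng, bump.size))
        if gap < 1:
            raise ValueError("gap_law must return gaps >= 1")
        chunks.append(np.zeros(gap))
        chunks.append(bump)
    chunks.append(np.zeros(max(2, int(gap_law(rng, 2)))))
    values = np.concatenate(chunks)
    if np.count_nonzero(values == 0) * 2 <= values.size:
        raise ValueError("gaps too short: median would leave the baseline")
    return TimeSeries(values, dt=dt, label="event_series")


def make_planted_population(
    n_neurons: int = 1000,
    group_sizes: tuple[int, int] = (100, 100),
    coupling: float = 1.0,
    noise_sd: float = 0.4,
    behavior_coupling: float = 0.25,
    T: int = 16384,
    dt: float = 1.0 / 3.0,
    rng_seed=None,
    tau: float = 1.2,
    s_bounds: tuple[float, float] = (1.0, 1e4),
) -> PlantedPopulation:
    """Population with two anticorrelated scale-free groups plus noise neurons.

    A signed switching signal alternates scale-free bumps between group A
    (positive) and group B (negative); the two latent drivers are the
    signal and its negation shifted to a common resting level C and
    rectified at zero:  A = max(C + x, 0),  B = max(C - x, 0).  Bumps are
    disjoint in time, so corr(A, B) = -1 and A + B is constant: averaging
    the two groups cancels their fluctuations, as in recordings where
    anticorrelated subsets hide scale-free dynamics from the population
    mean.  Each group neuron is coupling * latent + Gaussian noise whose SD
    is ``noise_sd`` in units of the latent's own SD; noise neurons are pure
    Gaussian.  Behavior channels reuse the group-A event times with
    independent per-event amplitude jitter (relative SD
    ``behavior_coupling``) plus a small sensor-noise floor.

    Defaults give a 1.5-hour recording at a 3 Hz frame rate (T = 16384,
    dt = 1/3 s) with within-group pairwise correlations near 0.5.
    """
    rng = _as_rng(rng_seed)
    if coupling <= 0:
        raise ValueError("coupling must be positive")
    ga, gb = group_sizes
    n_noise = n_neurons - ga - gb
    if n_noise < 0:
        raise ValueError("group sizes exceed n_neurons")
    s_lo, s_hi = s_bounds

    # alternate scale-free bumps between the groups along a fixed-length timeline
    x = np.zeros(T)
    seg_group: list[int] = []
    seg_slices: list[slice] = []
    profiles: list[np.ndarray] = []
    cursor = 0
    which = 0
    max_peak = 0.0
    while True:
        size = float(sample_truncated_powerlaw(1, tau, s_lo, s_hi, rng)[0])
        bump = _bump_profile(size, dt, "half-sine")
        gap = _default_gap(rng, bump.size)
        start = cursor + gap
        if start + bump.size + 2 > T:
            break
        sign = 1.0 if which == 0 else -1.0
        x[start : start + bump.size] = sign * bump
        seg_group.append(which)
        seg_slices.append(slice(start, start + bump.size))
        profiles.append(bump)
        max_peak = max(max_peak, float(bump.max()))
        cursor = start + bump.size
        which = 1 - which
    if np.count_nonzero(x == 0) * 2 <= T:
        raise ValueError("timeline overfull: latent medians would leave the resting level")

    c_rest = max_peak  # resting level high enough that rectification never clips
    latent_a = TimeSeries(np.maximum(c_rest + x, 0.0), dt=dt, label="latentA")
    latent_b = TimeSeries(np.maximum(c_rest - x, 0.0), dt=dt, label="latentB")

    sd_a = latent_a.values.std()
    sd_b = latent_b.values.std()
    activity = np.empty((n_neurons, T))
    membership = np.empty(n_neurons, dtype=object)
    activity[:ga] = coupling * latent_a.values + rng.normal(0.0, noise_sd * sd_a, (ga, T))
    membership[:ga] = "groupA"
    activity[ga : ga + gb] = coupling * latent_b.values + rng.normal(0.0, noise_sd * sd_b, (gb, T))
    membership[ga : ga + gb] = "groupB"
    activity[ga + gb :] = rng.normal(0.0, coupling * sd_a, (n_noise, T))
    membership[ga + gb :] = "noise"

    behaviors: dict[str, TimeSeries] = {}
    a_events = [i for i, g in enumerate(seg_group) if g == 0]
    # sensor-noise floor well below the smallest event so the head of the
    # behavioral size distribution is noise, not lost signal
    min_peak = min(float(profiles[i].max()) for i in a_events)
    for label in ("run_speed", "whisker"):
        beh = np.zeros(T)
        for i in a_events:
            jitter = rng.lognormal(0.0, behavior_coupling)
            beh[seg_slices[i]] = jitter * profiles[i]
        beh += rng.normal(0.0, 0.2 * min_peak, T)
        behaviors[label] = TimeSeries(beh, dt=dt, label=label)

    truth = {
        "tau_true": tau,
        "s_bounds": (s_lo, s_hi),
        "range_decades": float(np.log10(s_hi / s_lo)),
        "coupling": coupling,
        "noise_sd": noise_sd,
        "behavior_coupling": behavior_coupling,
        "n_events": len(seg_group),
        "n_events_A": len(a_events),
        "resting_level": c_rest,
        "dt": dt,
    }
    return PlantedPopulation(
        activity=activity,
        membership=membership,
        latent=(latent_a, latent_b),
        behaviors=behaviors,
        truth=truth,
    )
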