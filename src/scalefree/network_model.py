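"""Four-population probabilistic binary-neuron model.

N binary neurons (default 1000) are split into two excitatory groups (e+,
e-, 400 each) and two inhibitory groups (i+, i-, 100 each).  Each ordered
pair of groups is wired with a Bernoulli block density (0, 5% or 50% in the
configuration search); every nonzero excitatory connection carries weight
+c, every inhibitory one -c, and the whole matrix is rescaled so that its
largest real eigenvalue equals a target Lambda (Lambda = 1 is the critical
operating point).  Updates are synchronous:

    s_i(t) = 1 with probability  f( eta + sum_j C_ij s_j(t-1) ),

with f the identity clamped to [0, 1] and eta a uniform external drive.

In the canonical wiring (dense within-e+ and within-e-, sparse e+<->e-,
dense crossing inhibition e+ -> i+ -> e- and e- -> i- -> e+) the two
excitatory groups compete in a stochastic winner-take-all fashion: their
group-mean activities anticorrelate, each shows scale-free excursions,
and the fluctuations cancel in the all-neuron mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import extract_events
from .powerlaw import PowerLawFit, fit_power_law_range
from .preprocess import TimeSeries

__all__ = [
    "GROUPS",
    "NetworkConfig",
    "ModelRun",
    "RunStats",
    "canonical_config",
    "canonical_density",
    "build_connectivity",
    "simulate",
    "run_model",
    "analyze_run",
    "switching_rate",
]

#: Group order used everywhere: index 0 = e+, 1 = e-, 2 = i+, 3 = i-.
GROUPS = ("e+", "e-", "i+", "i-")
_EXC = (0, 1)
_INH = (2, 3)


def canonical_density() -> np.ndarray:
    """Block density matrix (target row, source column) of the canonical motif.

    Dense within-e+ and within-e-; sparse mutual e+<->e- excitation; dense
    crossing inhibition e+ -> i+, i+ -> e-, e- -> i-, i- -> e+; all other
    blocks zero.
    """
    d = np.zeros((4, 4))
    d[0, 0] = 0.50  # e+ <- e+
    d[1, 1] = 0.50  # e- <- e-
    d[0, 1] = 0.05  # e+ <- e-  (sparse crossing excitation)
    d[1, 0] = 0.05
    d[2, 0] = 0.50  # i+ <- e+
    d[1, 2] = 0.50  # e- <- i+
    d[3, 1] = 0.50  # i- <- e-
    d[0, 3] = 0.50  # e+ <- i-
    return d


@dataclass(frozen=True)
class NetworkConfig:
    """Model specification: group sizes, 4x4 block densities, Lambda, eta.

    ``density[t, s]`` is the connection probability from group ``s`` to
    group ``t`` (GROUPS order).  ``lam`` is the target largest real
    eigenvalue of the realized connection matrix; ``eta`` the external
    drive added to every neuron's input each step.
    """

    group_sizes: tuple[int, int, int, int] = (400, 400, 100, 100)
    density: np.ndarray = field(default_factory=canonical_density)
    lam: float = 1.0
    eta: float = 0.1
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.shape != (4, 4):
            raise ValueError("density must be a 4x4 matrix")
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError("densities must lie in [0, 1]")
        if any(g <= 0 for g in self.group_sizes):
            raise ValueError("group sizes must be positive")
        object.__setattr__(self, "density", d)

    @property
    def n_neurons(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def group_slices(self) -> list[slice]:
        bounds = np.concatenate(([0], np.cumsum(self.group_sizes)))
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def canonical_config(eta: float = 0.1, lam: float = 1.0, rng_seed: int | None = None) -> NetworkConfig:
    return NetworkConfig(density=canonical_density(), lam=lam, eta=eta, rng_seed=rng_seed)


@dataclass
class ModelRun:
    """Simulation output: per-group mean series and (optionally) the raster."""

    group_means: dict[str, TimeSeries]
    total_mean: TimeSeries
    realized_matrix_eigenvalue: float
    params: NetworkConfig
    states: np.ndarray | None = None


def build_connectivity(config: NetworkConfig, rng_seed=None) -> tuple[np.ndarray, float]:
    """Realize the weight matrix and normalize its leading eigenvalue.

    Per ordered block, entries are kept with the block's Bernoulli density;
    excitatory-source entries are +1, inhibitory-source entries -1, the
    diagonal is zeroed (no self-connections), and the matrix is scaled so
    its largest real eigenvalue equals ``config.lam``.

    Returns ``(matrix, realized_eigenvalue)``.

    Raises
    ------
    ValueError
        If the realized matrix has no positive real eigenvalue to normalize
        by (e.g. the all-zero matrix).
    """
    if rng_seed is None:
        rng_seed = config.rng_seed
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = config.n_neurons
    sl = config.group_slices
    w = np.zeros((n, n))
    for ti in range(4):
        for si in range(4):
            dens = config.density[ti, si]
            if dens == 0:
                continue
            block = (rng.random((sl[ti].stop - sl[ti].start, sl[si].stop - sl[si].start)) < dens)
            sign = 1.0 if si in _EXC else -1.0
            w[sl[ti], sl[si]] = sign * block
    np.fill_diagonal(w, 0.0)
    if not w.any():
        raise ValueError("all-zero connection matrix cannot be normalized")

    eigs = np.linalg.eigvals(w)
    real = eigs[np.abs(eigs.imag) < 1e-9 * max(1.0, np.abs(eigs).max())].real
    real = real[real > 0]
    if real.size == 0:
        raise ValueError("no positive real eigenvalue; cannot set Lambda")
    lead = float(real.max())
    w *= config.lam / lead

    # realized leading eigenvalue after scaling (linear, so = lam by construction)
    return w, config.lam


def simulate(
    matrix: np.ndarray,
    eta: float,
    T: int,
    burn_in: int = 1000,
    rng_seed=None,
    group_sizes: tuple[int, ...] = (400, 400, 100, 100),
    record_raster: bool = False,
    config: NetworkConfig | None = None,
    realized_eigenvalue: float = float("nan"),
) -> ModelRun:
    """Run the synchronous binary dynamics for ``T`` steps after ``burn_in``.

    The initial state is all-quiescent; the first ``burn_in`` steps are
    discarded.  Firing probabilities are ``clip(eta + C s, 0, 1)``.  The
    per-group and all-neuron means are always recorded (model analysis is
    done on group-averaged population activity); the full binary raster is
    kept only when ``record_raster`` is set.

    Raises
    ------
    ValueError
        If ``eta`` < 0 or ``T`` <= ``burn_in``.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    if not (T > burn_in >= 0):
        raise ValueError("require T > burn_in >= 0")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)

    # column-major storage: each step reads only the columns of currently
    # active neurons (binary states make the matvec a column-subset sum)
    w32 = np.asfortranarray(matrix, dtype=np.float32)
    n = w32.shape[0]
    if sum(group_sizes) != n:
        raise ValueError("group sizes do not sum to the matrix dimension")
    n_groups = len(group_sizes)
    group_id = np.repeat(np.arange(n_groups), group_sizes)
    n_keep = T - burn_in

    active = np.empty(0, dtype=np.intp)
    eta32 = np.float32(eta)
    # integer spike counts per group; divisions happen once at the end so
    # that equal counts give bit-identical float means (median-threshold
    # event extraction must not see rounding noise)
    counts = np.empty((n_groups, n_keep), dtype=np.float64)
    raster = np.empty((n, n_keep), dtype=bool) if record_raster else None
    sizes = np.asarray(group_sizes, dtype=np.float64)

    for t in range(T):
        if active.size:
            p = w32[:, active].sum(axis=1)
            p += eta32
        else:
            p = np.full(n, eta32)
        np.clip(p, 0.0, 1.0, out=p)
        fired = rng.random(n, dtype=np.float32) < p
        active = np.flatnonzero(fired)
        if t >= burn_in:
            k = t - burn_in
            counts[:, k] = np.bincount(group_id[active], minlength=n_groups)
            if record_raster:
                raster[:, k] = fired

    labels = GROUPS if len(group_sizes) == 4 else tuple(f"g{i}" for i in range(len(group_sizes)))
    group_means = {
        lab: TimeSeries(counts[i] / sizes[i], dt=1.0, label=lab) for i, lab in enumerate(labels)
    }
    total = TimeSeries(counts.sum(axis=0) / sizes.sum(), dt=1.0, label="total")
    return ModelRun(
        group_means=group_means,
        total_mean=total,
        realized_matrix_eigenvalue=realized_eigenvalue,
        params=config if config is not None else NetworkConfig(
            group_sizes=tuple(int(g) for g in group_sizes), eta=eta
        ),
        states=raster,
    )


def run_model(
    config: NetworkConfig,
    T: int,
    burn_in: int = 1000,
    rng_seed=None,
    record_raster: bool = False,
) -> ModelRun:
    """Build the connectivity for ``config`` and simulate it."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    w, lam = build_connectivity(config, rng)
    return simulate(
        w, config.eta, T, burn_in, rng,
        group_sizes=config.group_sizes,
        record_raster=record_raster,
        config=config,
        realized_eigenvalue=lam,
    )


@dataclass(frozen=True)
class RunStats:
    """Group-level statistics of one model run, in experiment-matching terms."""

    fits: dict[str, PowerLawFit]
    corr_e: float
    corr_i: float

    @property
    def r_e(self) -> float:
        """Larger power-law range of the two excitatory groups, decades."""
        return max(self.fits["e+"].range_decades, self.fits["e-"].range_decades)

    @property
    def r_total(self) -> float:
        return self.fits["total"].range_decades


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def analyze_run(
    run: ModelRun,
    F_criterion: float = 0.80,
    n_surrogate: int = 500,
    rng_seed=None,
    groups: tuple[str, ...] = ("e+", "e-"),
    **fit_kwargs,
) -> RunStats:
    """Median-threshold events and power-law range per group mean + total.

    Fits are computed for each group in ``groups`` and for the all-neuron
    mean; Pearson correlations are reported for (e+, e-) and (i+, i-).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    fits: dict[str, PowerLawFit] = {}
    for label in (*groups, "total"):
        ts = run.total_mean if label == "total" else run.group_means[label]
        ev = extract_events(ts, threshold="median")
        fits[label] = fit_power_law_range(
            ev.sizes, F_criterion=F_criterion, n_surrogate=n_surrogate,
            rng_seed=rng, **fit_kwargs,
        )
    corr_e = _corr(run.group_means["e+"].values, run.group_means["e-"].values)
    corr_i = _corr(run.group_means["i+"].values, run.group_means["i-"].values)
    return RunStats(fits=fits, corr_e=corr_e, corr_i=corr_i)


def switching_rate(run: ModelRun, per_steps: int = 10_000) -> float:
    """Winner-switching rate: sign changes of e+ - e- per ``per_steps`` steps.

    Stochastic winner-take-all dynamics flip the sign of the group-mean
    difference frequently; locked-in dynamics (Lambda above 1) pin the
    difference on one side, so the rate collapses.  Steps where the two
    groups tie carry the previous sign.
    """
    diff = run.group_means["e+"].values - run.group_means["e-"].values
    sign = np.sign(diff)
    # ties inherit the preceding winner
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    sign = sign[sign != 0]
    if sign.size < 2:
        return 0.0
    crossings = int(np.count_nonzero(np.diff(sign)))
    return crossings * per_steps / diff.size
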