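"""Constrained search over 4x4 block-connectivity configurations.

Each of the 16 ordered group pairs is assigned one of three densities:
disconnected (0), sparse (5%) or dense (50%), giving 3^16 (about 43
million) configurations.  Admissibility constraints prune unrealistic
circuits before simulation:

1. both e+ and e- have nonzero within-group connectivity;
2. no disconnected components: the block digraph (self-loops ignored) is
   weakly connected, so every group is reachable by at least one connection;
3. at least one excitatory-to-inhibitory connection;
4. at least one inhibitory-to-excitatory connection.

Surviving configurations can be simulated (at Lambda = 1) and classified
against experiment-matching criteria, either strict (anticorrelated e and i
pairs, e-group power-law range > 3.5 decades, total-population range < 2)
or loose (range ratio >= 1.4 replaces the absolute range bounds).  A purely
structural motif predicate - segregated excitatory groups plus one of two
dense crossing-inhibition motifs - predicts matching configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import NetworkConfig, RunStats, analyze_run, run_model

__all__ = [
    "DENSITY_LEVELS",
    "ConfigVerdict",
    "admissible",
    "count_admissible",
    "classify",
    "motif_predicate",
    "random_admissible_configs",
    "shotgun_config_search",
]

#: Allowed block densities in the configuration search.
DENSITY_LEVELS = (0.0, 0.05, 0.50)

_E = (0, 1)  # e+, e-
_I = (2, 3)  # i+, i-


@dataclass(frozen=True)
class ConfigVerdict:
    """Outcome of simulating and classifying one sampled configuration."""

    density: np.ndarray
    stats: RunStats | None
    strict_match: bool
    loose_match: bool
    has_motif: bool
    error: str | None = None


def _check_density(density: np.ndarray) -> np.ndarray:
    d = np.asarray(density, dtype=float)
    if d.shape != (4, 4):
        raise ValueError("density must be a 4x4 matrix")
    if not np.isin(d, DENSITY_LEVELS).all():
        raise ValueError(f"densities must be drawn from {DENSITY_LEVELS}")
    return d


def _weakly_connected(adj: np.ndarray) -> bool:
    """Weak connectivity of the 4-node block digraph, self-loops ignored."""
    und = adj | adj.T
    np.fill_diagonal(und, False)
    seen = np.zeros(4, dtype=bool)
    seen[0] = True
    frontier = [0]
    while frontier:
        u = frontier.pop()
        for v in np.flatnonzero(und[u]):
            if not seen[v]:
                seen[v] = True
                frontier.append(v)
    return bool(seen.all())


def admissible(density: np.ndarray) -> bool:
    """True iff the configuration passes all four structural constraints."""
    d = _check_density(density)
    adj = d > 0
    if not (adj[0, 0] and adj[1, 1]):
        return False
    if not any(adj[t, s] for t in _I for s in _E):
        return False
    if not any(adj[t, s] for t in _E for s in _I):
        return False
    return _weakly_connected(adj)


def count_admissible() -> int:
    """Exhaustive count of admissible configurations among all 3^16.

    Pure combinatorics: admissibility depends only on the zero/nonzero
    pattern of the 16 blocks, so the count enumerates the 2^16 binary
    patterns and weights each admissible one by 2^(number of nonzero
    blocks), the number of ways to assign sparse/dense to its edges.
    """
    total = 0
    for bits in range(1 << 16):
        adj = np.array(
            [[(bits >> (4 * t + s)) & 1 for s in range(4)] for t in range(4)],
            dtype=bool,
        )
        if admissible(np.where(adj, 0.50, 0.0)):
            total += 1 << int(adj.sum())
    return total


def classify(stats: RunStats, mode: str = "strict") -> bool:
    """Experiment-matching criteria on a run's group statistics.

    strict: corr(e+, e-) < -0.5, corr(i+, i-) < -0.5, max e-group range
    > 3.5 decades, total-population range < 2 decades.
    loose: corr(e+, e-) < -0.5, corr(i+, i-) < -0.2, max e-group range
    >= 1.4 x total-population range.
    """
    if mode == "strict":
        return (
            stats.corr_e < -0.5
            and stats.corr_i < -0.5
            and stats.r_e > 3.5
            and stats.r_total < 2.0
        )
    if mode == "loose":
        return (
            stats.corr_e < -0.5
            and stats.corr_i < -0.2
            and stats.r_e >= 1.4 * stats.r_total
        )
    raise ValueError(f"unknown mode {mode!r}")


def motif_predicate(density: np.ndarray) -> bool:
    """Structural signature shared by all experiment-matching circuits.

    Requires segregated excitatory groups (dense within-e+ and within-e-,
    both e+<->e- blocks at most sparse) plus dense crossing inhibition in
    both directions: some inhibitory group iX with e+ -> iX -> e- dense,
    and some iY (possibly the same group) with e- -> iY -> e+ dense.
    """
    d = _check_density(density)
    dense = 0.50
    if not (d[0, 0] == dense and d[1, 1] == dense):
        return False
    if d[0, 1] > 0.05 or d[1, 0] > 0.05:
        return False
    cross_plus = any(d[i, 0] == dense and d[1, i] == dense for i in _I)  # e+ -> iX -> e-
    cross_minus = any(d[i, 1] == dense and d[0, i] == dense for i in _I)  # e- -> iY -> e+
    return cross_plus and cross_minus


def random_admissible_configs(n: int, rng_seed=None) -> list[np.ndarray]:
    """Sample ``n`` distinct admissible density matrices uniformly at random.

    Rejection sampling over the 3^16 assignments, without replacement.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if n < 1:
        raise ValueError("n must be >= 1")
    levels = np.array(DENSITY_LEVELS)
    seen: set[bytes] = set()
    out: list[np.ndarray] = []
    while len(out) < n:
        digits = rng.integers(0, 3, size=16)
        key = digits.tobytes()
        if key in seen:
            continue
        seen.add(key)
        d = levels[digits].reshape(4, 4)
        if admissible(d):
            out.append(d)
    return out


def shotgun_config_search(
    n_samples: int,
    sim_params: dict | None = None,
    rng_seed=None,
) -> list[ConfigVerdict]:
    """Simulate and classify a random sample of admissible configurations.

    Each sampled configuration is realized at Lambda = 1, simulated, and
    classified strictly and loosely; the motif predicate is evaluated
    structurally.  Per-configuration simulation failures (e.g. no positive
    real eigenvalue to normalize) are recorded and the search continues.

    ``sim_params`` may override ``T``, ``burn_in``, ``eta``, ``group_sizes``,
    ``F_criterion``, ``n_surrogate`` and ``min_tail``.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    params = dict(T=50_000, burn_in=1000, eta=0.1, group_sizes=(400, 400, 100, 100),
                  F_criterion=0.80, n_surrogate=500, min_tail=30)
    params.update(sim_params or {})

    verdicts: list[ConfigVerdict] = []
    for density in random_admissible_configs(n_samples, rng):
        motif = motif_predicate(density)
        cfg = NetworkConfig(
            group_sizes=tuple(params["group_sizes"]),
            density=density, lam=1.0, eta=params["eta"],
        )
        try:
            run = run_model(cfg, T=params["T"], burn_in=params["burn_in"], rng_seed=rng)
            stats = analyze_run(
                run,
                F_criterion=params["F_criterion"],
                n_surrogate=params["n_surrogate"],
                min_tail=params["min_tail"],
                rng_seed=rng,
            )
            verdicts.append(ConfigVerdict(
                density=density, stats=stats,
                strict_match=classify(stats, "strict"),
                loose_match=classify(stats, "loose"),
                has_motif=motif,
            ))
        except ValueError as exc:  # degenerate spectrum etc.
            verdicts.append(ConfigVerdict(
                density=density, stats=None,
                strict_match=False, loose_match=False,
                has_motif=motif, error=str(exc),
            ))
    return verdicts
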