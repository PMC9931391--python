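"""Shared fixtures: heavy simulations are session-scoped and reused."""

import numpy as np
import pytest

from scalefree import analyze_run, canonical_config, make_planted_population, run_model


@pytest.fixture(scope="session")
def planted():
    """Default planted population: 100 A + 100 B + 800 noise neurons, 1.5 h at 3 Hz."""
    return make_planted_population(rng_seed=11)


@pytest.fixture(scope="session")
def canonical_run():
    """Canonical winner-take-all run: Lambda=1, mid-sweep drive, 1e5 kept steps."""
    return run_model(canonical_config(rng_seed=101), T=101_000, burn_in=1000, rng_seed=102)


@pytest.fixture(scope="session")
def canonical_stats(canonical_run):
    return analyze_run(canonical_run, rng_seed=103)
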