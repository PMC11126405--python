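import numpy as np
import pytest

from cnclust import (
    SimulationSpec,
    make_archetypes,
    make_grid,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_grid():
    """A 460-probe grid over all 23 chromosomes (20 probes/chromosome scale)."""
    return make_grid(460)


@pytest.fixture(scope="session")
def archetypes(small_grid):
    return make_archetypes(
        grid=small_grid,
        segments_per_class=3,
        min_len=3,
        max_len=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def balanced_cohort(archetypes):
    """Noise-free balanced cohort: every profile equals its class archetype."""
    spec = SimulationSpec(
        n_samples=60,
        proportions=np.full(10, 0.1),
        sigma=0.0,
        missing_fraction=0.0,
        seed=11,
    )
    return simulate_cohort(archetypes, spec)


@pytest.fixture(scope="session")
def noisy_cohort(archetypes):
    spec = SimulationSpec(
        n_samples=200,
        proportions=np.full(10, 0.1),
        sigma=0.2,
        missing_fraction=0.02,
        seed=12,
    )
    return simulate_cohort(archetypes, spec)
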