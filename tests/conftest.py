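import hypothesis
import numpy as np
import pytest

from prodland import cme_simulator as sim
from prodland.landscape_io import (
    ProbabilityLandscape,
    SpeciesDescriptor,
    StateSpace,
)

hypothesis.settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20170215)


def random_landscape(rng, n_species=3, max_copies=4, n_states=50, n_times=4):
    """A random but valid landscape over a random subset of a copy-number
    hypercube (for brute-force oracle tests)."""
    species = [
        SpeciesDescriptor(f"P{j}", max_copies=max_copies)
        for j in range(n_species)
    ]
    cube = np.stack(
        np.meshgrid(*[np.arange(max_copies + 1)] * n_species, indexing="ij"),
        axis=-1,
    ).reshape(-1, n_species)
    rows = rng.choice(cube.shape[0], size=min(n_states, cube.shape[0]), replace=False)
    states = cube[np.sort(rows)]
    probs = rng.random((states.shape[0], n_times))
    probs /= probs.sum(axis=0)
    return ProbabilityLandscape(
        StateSpace(species, states), np.arange(n_times, dtype=float), probs
    )


@pytest.fixture
def small_random_landscape(rng):
    return random_landscape(rng)


@pytest.fixture(scope="session")
def toggle_full_statespace():
    """Full toggle-switch enumeration at the production buffer sizes."""
    network, _ = sim.toggle_switch_preset((120, 240))
    return sim.enumerate_states(network)


@pytest.fixture(scope="session")
def reduced_toggle_landscape():
    """Reduced toggle (buffers 12, 12) propagated over 50 unit time steps."""
    network, initial = sim.toggle_switch_preset((12, 12))
    return sim.run_simulation(network, initial, np.arange(0.0, 51.0))


@pytest.fixture(scope="session")
def bistable_toggle_landscape():
    """Symmetric toggle at buffers (30, 30) run into its four-peak regime."""
    network, initial = sim.toggle_switch_preset((30, 30))
    return sim.run_simulation(network, initial, np.arange(0.0, 201.0, 25.0))
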