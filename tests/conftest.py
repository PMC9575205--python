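import numpy as np
import pytest

from pioneerindex import (
    DoseGrid,
    SignalProfile,
    SimulationConfig,
    binding_isotherm,
    simulate_binding_dataset,
)


@pytest.fixture(scope="session")
def grid():
    return DoseGrid()


@pytest.fixture(scope="session")
def small_experiment():
    """A modest noisy experiment reused across integration tests."""
    cfg = SimulationConfig(n_accessible=40, n_inaccessible=40, noise_cv=0.1, seed=7)
    return simulate_binding_dataset(cfg)


def make_profile(dox50, grid, cv=0.0, amplitude=10.0, rng=None, site_id="s"):
    """Raw RPKM profile following the binding isotherm, optionally noisy."""
    shape = binding_isotherm(grid.array, dox50)
    noise = np.exp(rng.normal(0, cv, len(grid))) if (rng is not None and cv > 0) else 1.0
    return SignalProfile(site_id, amplitude * shape * noise)
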