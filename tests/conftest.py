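import numpy as np
import pytest

import regretchoice as rc


@pytest.fixture(scope="session")
def default_dataset():
    """One full-scale simulated experiment (50 subjects x 4 cells x 48 trials)."""
    return rc.simulate_dataset(rc.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick dataset for structural tests (12 subjects x 4 cells x 16 trials)."""
    return rc.simulate_dataset(rc.SimulationConfig(seed=3, n_subjects=12, n_trials_per_condition=16))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
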