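import numpy as np
import pytest

import wearload as wl


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_config():
    """Fast generator settings: 6 participants, short trials."""
    return wl.SimulationConfig(n_participants=6, trial_duration_s=90.0, seed=11)


@pytest.fixture
def summary_table():
    """A study-sized observation table drawn from the generative model."""
    return wl.simulate_summary_dataset(wl.SimulationConfig(seed=7))


@pytest.fixture
def noiseless_table():
    cfg = wl.SimulationConfig(sd_intercept=0.0, sd_slope=0.0, sd_residual=0.0, seed=5)
    return wl.simulate_summary_dataset(cfg)
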