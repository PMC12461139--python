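import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dyadcausal.var as dv
from dyadcausal.io import DyadEpoch
from dyadcausal.synthetic import SimulationConfig

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

FS = 10.17


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    return dv.FrequencyGrid.linspace(FS, 257)


@pytest.fixture
def small_config():
    """Simulation config reduced for fast tests (same signal structure)."""
    return SimulationConfig(n_trials_per_condition=3, tail_padding=30.0)


def make_epoch(data: np.ndarray, fs: float = FS, condition: str = "hand",
               region: str = "M1", dyad_id: str = "dyadXX",
               trial: int = 0) -> DyadEpoch:
    n = data.shape[1] // 2
    return DyadEpoch(data=data, n_per_participant=n, fs=fs,
                     condition=condition, region=region, dyad_id=dyad_id,
                     trial_index=trial)


@pytest.fixture
def white_epoch(rng):
    """Uncoupled white-noise dyad epoch, 2 channels per participant."""
    return make_epoch(rng.standard_normal((204, 4)))


@pytest.fixture
def coupled_epoch(rng):
    """Strongly coupled broadband dyad epoch: Imitator copies Model at lag 2."""
    L, lag = 204, 2
    s = rng.standard_normal(L + lag)
    m = s[lag:] + 0.3 * rng.standard_normal(L)
    i = s[:L] + 0.3 * rng.standard_normal(L)
    return make_epoch(np.column_stack([m, i]))
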