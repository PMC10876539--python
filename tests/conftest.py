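import numpy as np
import pytest

from bandittrial import build_catalog, run_trial
from bandittrial.config import SimulatorParams, TrialConfig


@pytest.fixture(scope="session")
def catalog():
    return build_catalog(n_templates_per_set=2, seed=0)


@pytest.fixture(scope="session")
def small_trial():
    """A compact bandit-policy trial reused across analysis-stage tests."""
    cfg = TrialConfig(n_patients=14, follow_up_days=40, seed=11)
    return run_trial(cfg)


@pytest.fixture(scope="session")
def random_trial():
    """A full-size non-adaptive trial (fast path) for responsiveness stats."""
    cfg = TrialConfig(n_patients=58, follow_up_days=180, policy="random", seed=5)
    return run_trial(cfg)


@pytest.fixture(scope="session")
def clean_trial():
    """Trial with no disconnection, for exact event-count accounting."""
    cfg = TrialConfig(
        n_patients=12,
        follow_up_days=30,
        seed=3,
        simulator=SimulatorParams(disconnect_rate=0.0),
    )
    return run_trial(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
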