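import numpy as np
import pytest

from screamsleep.synthdata import SessionConfig, generate_session, generate_stimulus_set


@pytest.fixture(scope="session")
def stimulus_set():
    """One 8+8 pitch-matched stimulus set, shared across tests."""
    return generate_stimulus_set(n_per_condition=8, seed=0)


@pytest.fixture(scope="session")
def nrem_session(stimulus_set):
    """A two-block NREM-only session with default effect sizes."""
    cfg = SessionConfig(wake_blocks=0, nrem_blocks=2, seed=11)
    return generate_session(cfg, stimulus_set, participant=0)


@pytest.fixture(scope="session")
def wake_session(stimulus_set):
    """A one-block wake session with a strong evoked potential and low noise
    (for latency checks that need a clean trial average)."""
    cfg = SessionConfig(wake_blocks=1, nrem_blocks=0, seed=5,
                        erp_amplitude=25.0, background_sd=2.0,
                        theta_burst_amplitude=0.0)
    return generate_session(cfg, stimulus_set, participant=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
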