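import numpy as np
import pytest

from tunnelmea.synthetic import SimConfig, simulate_session


@pytest.fixture(scope="session")
def session_5t():
    """One default 5-tunnel stimulation session, shared across tests."""
    return simulate_session(SimConfig(n_tunnels=5, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
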