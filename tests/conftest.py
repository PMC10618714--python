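import numpy as np
import pytest

from latentemg.evaluate import prepare_session
from latentemg.synth import WorldConfig, generate_session, generate_world


@pytest.fixture(scope="session")
def twin_world():
    """Two monkey-like subjects sharing latent structure through random mixing."""
    return generate_world(WorldConfig(seed=11, n_subjects=2))


@pytest.fixture(scope="session")
def twin_sessions(twin_world):
    a = generate_session(twin_world, 0, 0, 8, "monkey")
    b = generate_session(twin_world, 1, 0, 8, "monkey")
    return a, b


@pytest.fixture(scope="session")
def twin_prepared(twin_sessions):
    a, b = twin_sessions
    return prepare_session(a), prepare_session(b)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
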