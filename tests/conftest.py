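import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import settings

import stsreflex as sr

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def model_and_state():
    return sr.build_model()


@pytest.fixture(scope="session")
def model(model_and_state):
    return model_and_state[0]


@pytest.fixture(scope="session")
def seated_state(model_and_state):
    return model_and_state[1].copy()


@pytest.fixture(scope="session")
def sts2():
    """2-phase high-level model (shared so the kernels compile once)."""
    return sr.ReflexSTS(controller_type="2phase")


@pytest.fixture(scope="session")
def sts4():
    return sr.ReflexSTS(controller_type="4phase")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
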