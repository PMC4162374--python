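import numpy as np
import pytest

from hetnet.core import NeuronConstants, default_spec
from hetnet.presets import make_fixture


@pytest.fixture(scope="session")
def constants():
    return NeuronConstants()


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def single_neuron():
    real, drive = make_fixture("single-neuron")
    return real


@pytest.fixture(scope="session")
def tiny_ei():
    real, drive = make_fixture("tiny-EI")
    return real


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
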