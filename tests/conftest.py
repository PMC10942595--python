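import numpy as np
import pytest

from transrep import presets
from transrep.circuit import default_circuit, default_growth


@pytest.fixture
def original_kinetics():
    return presets.KINETICS_PRESETS["original"]


@pytest.fixture
def circuit_model():
    return default_circuit()


@pytest.fixture
def growth_model():
    return default_growth()


@pytest.fixture
def rng():
    return np.random.default_rng(20240216)
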