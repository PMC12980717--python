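import numpy as np
import pytest

from rt2des import PropagationConfig, make_fixture
from rt2des.fields import Pulse, intensity_to_amplitude


@pytest.fixture
def benzene():
    return make_fixture("benzene_like")


@pytest.fixture
def chlorophyll():
    return make_fixture("chlorophyll_like")


@pytest.fixture
def dimer():
    return make_fixture("dimer_like")


@pytest.fixture
def weak_pulse():
    """2 fs pulse at the benzene bright-state energy, standard intensity."""
    return Pulse.from_lab(0.0, 5.61, 0.0, intensity_to_amplitude(5.01e9), 2.0)


@pytest.fixture
def short_cfg():
    """Short closed-system run for cheap pipeline tests."""
    return PropagationConfig.from_lab(t_final_fs=60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
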