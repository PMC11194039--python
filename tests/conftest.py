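import numpy as np
import pytest

from aoncb import NeuronSpec


@pytest.fixture
def neuron():
    """Reference membrane: tau = 15 ms, Ve = 60 mV, Vi = -10 mV, leak at 0."""
    return NeuronSpec(tau=15e-3, Ve=60.0, Vi=-10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
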