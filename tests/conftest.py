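import numpy as np
import pytest

from wormcircuit.connectome import Connectome, Neuron
from wormcircuit.model import default_params
from wormcircuit.synthetic import ToySpec, make_toy_connectome, oscillator_fixture


def three_neuron_connectome(gap_ab=2.0, chem_ac=5.0, inhibitory_b=False):
    neurons = [
        Neuron("A", "A", "sensory", False, 0),
        Neuron("B", "B", "inter", inhibitory_b, 1),
        Neuron("C", "C", "motor", False, 2),
    ]
    gap = np.zeros((3, 3))
    gap[0, 1] = gap[1, 0] = gap_ab
    chem = np.zeros((3, 3))
    chem[0, 2] = chem_ac
    return Connectome(neurons, gap, chem, version_tag="test3")


@pytest.fixture
def conn3():
    return three_neuron_connectome()


@pytest.fixture
def single_neuron():
    return Connectome(
        [Neuron("A", "A", "inter", False, 0)], np.zeros((1, 1)), np.zeros((1, 1))
    )


@pytest.fixture
def params_fast():
    """Short-run defaults for cheap dynamics tests."""
    return default_params(duration=2.0)


@pytest.fixture(scope="session")
def fixture_toy():
    return oscillator_fixture()


@pytest.fixture
def feedforward_toy():
    return make_toy_connectome(
        ToySpec(1, 1, 1, 1, 0, gap_weight=2.0, chem_weight=3.0)
    )
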