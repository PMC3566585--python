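import numpy as np
import pytest

from dcmodes import (CouplingParameters, HemodynamicParameters,
                     InputFunctions, ModelSpec)
from dcmodes.workbench import SimulationProtocol, make_block_design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec2():
    return ModelSpec(n_nodes=2, n_inputs=1, driven_nodes=(0,))


@pytest.fixture
def coupling2():
    return CouplingParameters(
        A=np.array([[-0.5, 0.2], [0.1, -0.5]]),
        C=np.array([[0.4], [0.0]]))


@pytest.fixture
def hemo2():
    return HemodynamicParameters(n_nodes=2)


@pytest.fixture
def protocol2():
    return SimulationProtocol(n_nodes=2, n_volumes=40, n_driven=1, seed=1)


@pytest.fixture
def inputs2(protocol2):
    return make_block_design(protocol2)


@pytest.fixture
def zero_inputs2(protocol2):
    steps = protocol2.n_volumes * protocol2.steps_per_tr
    return InputFunctions(u=np.zeros((steps, 1)),
                         dt_micro=protocol2.dt_micro,
                         TR=protocol2.TR, n_volumes=protocol2.n_volumes)
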