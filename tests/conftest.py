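import numpy as np
import pytest

from hdcompass import (NetworkParams, RingAttractor, build_connectome,
                       default_calibration)


@pytest.fixture(scope="session")
def calib():
    return default_calibration()


@pytest.fixture(scope="session")
def params(calib):
    return calib.params


@pytest.fixture(scope="session")
def connectome(params):
    return build_connectome(params)


@pytest.fixture(scope="session")
def settled_bump(connectome):
    """A network with a bump ignited at 90 deg and settled for 2 s."""
    net = RingAttractor(connectome, seed=0)
    net.initialize_bump(90.0)
    for _ in range(1700):
        net.step()
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
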