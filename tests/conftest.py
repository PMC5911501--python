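import numpy as np
import pytest

from valvefsi.fixtures import unit_square_mesh
from valvefsi.geometry import generate_2d_valve_channel


@pytest.fixture(scope="session")
def square8():
    return unit_square_mesh(8)


@pytest.fixture(scope="session")
def channel():
    """Small 2D valve channel shared by contact/postprocess tests."""
    return generate_2d_valve_channel(80.0, 20.0, 17.0, 1.5, 2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20180416)
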