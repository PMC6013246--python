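import numpy as np
import pytest

from myopos import CellGeometry, make_model


@pytest.fixture(scope="session")
def m1_model():
    """Repulsive-decreasing internuclear, attractive-increasing side."""
    return make_model(1, -1, -1, 1, 1, -1, M_S=2.0, M_P=3.2)


@pytest.fixture(scope="session")
def m2_model():
    """Repulsive-decreasing internuclear and side (the calibrated model)."""
    return make_model(1, -1, 1, -1, 1, -1, M_S=2.2, M_P=3.2)


@pytest.fixture(scope="session")
def wide_cell():
    return CellGeometry(40.0, 250.0, 15)


@pytest.fixture(scope="session")
def thin_cell():
    return CellGeometry(25.0, 250.0, 9)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
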