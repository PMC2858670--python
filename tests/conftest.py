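import numpy as np
import pytest

from turingfold import make_icosphere, compute_geometry


@pytest.fixture(scope="session")
def icosphere3():
    return make_icosphere(3)


@pytest.fixture(scope="session")
def icosphere4():
    return make_icosphere(4)


@pytest.fixture(scope="session")
def geom3(icosphere3):
    return compute_geometry(icosphere3)


@pytest.fixture(scope="session")
def geom4(icosphere4):
    return compute_geometry(icosphere4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
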