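import numpy as np
import pytest

from rdcfold.simulate import make_fixture

HELIX_T = [(None, None)] + [(-60.0, -45.0)] * 10 + [(None, None)]


@pytest.fixture(scope="session")
def helix15():
    return make_fixture("helix15")


@pytest.fixture(scope="session")
def hairpin12():
    return make_fixture("hairpin12")


@pytest.fixture(scope="session")
def hth20():
    return make_fixture("helix_turn_helix20")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2**31)))).as_matrix()
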