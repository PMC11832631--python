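import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helixfit import SaupeTensor, build_ideal_helix


@pytest.fixture(scope="session")
def ideal18():
    """18-residue default ideal helix (5 full turns)."""
    return build_ideal_helix(18)


def random_saupe(rng, da_range=(2.0, 15.0)):
    """Random Saupe tensor with uniform rhombicity and Haar orientation."""
    da = rng.uniform(*da_range) * rng.choice([-1.0, 1.0])
    rh = rng.uniform(0.0, 2.0 / 3.0)
    rot = Rotation.random(random_state=rng)
    return SaupeTensor.from_params(da, rh, rot)


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
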