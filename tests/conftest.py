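import numpy as np
import pytest

from liporsc.phantoms import make_asymmetric_phantom, make_channel_phantom
from liporsc.sim_micrograph import BilayerProfile, CTFParams


@pytest.fixture(scope="session")
def profile():
    return BilayerProfile()


@pytest.fixture(scope="session")
def ctf_default():
    return CTFParams(pixel_size_a=2.1)


@pytest.fixture(scope="session")
def channel_phantom_64():
    """C4 tetrameric channel phantom, 64^3 voxels at 4.2 A."""
    return make_channel_phantom(box=64, pixel_size=4.2)


@pytest.fixture(scope="session")
def asymmetric_phantom_64():
    """Asymmetric blob phantom (orientations uniquely defined)."""
    return make_asymmetric_phantom(box=64, pixel_size=4.2, seed=7)


@pytest.fixture(scope="session")
def channel_phantom_128():
    """C4 channel phantom at the unbinned simulation scale (128^3 at 2.1 A)."""
    return make_channel_phantom(box=128, pixel_size=2.1)


def random_orientation(rng):
    """Uniform orientation: cos(theta) uniform, phi/psi uniform."""
    theta = np.degrees(np.arccos(rng.uniform(-1.0, 1.0)))
    return theta, rng.uniform(0, 360.0), rng.uniform(0, 360.0)
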