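import numpy as np
import pytest

from optsurf.phantoms import EllipsePrimitive, Phantom, axis_coords, make_opaque_phantom


@pytest.fixture(scope="session")
def sphere_phantom():
    """Opaque gray sphere (radius 0.5) on a 48^3 grid, one channel."""
    prim = EllipsePrimitive(center=(0, 0, 0), semi_axes=(0.5, 0.5, 0.5),
                            reflectance=(0.6,))
    return make_opaque_phantom([prim], (48, 48, 48), channels=1)


@pytest.fixture(scope="session")
def disk_image():
    """Centered uniform disk (mu=1, radius 0.4) on a 128^2 grid."""
    n = 128
    c = axis_coords(n)
    img = ((c[None, :] ** 2 + c[:, None] ** 2) <= 0.16).astype(float)
    return img


@pytest.fixture(scope="session")
def disk_phantom(disk_image):
    return Phantom(attenuation=disk_image)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
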