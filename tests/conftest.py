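import numpy as np
import pytest

from mifcontext.simulate import InterfaceSpec, make_geometry


@pytest.fixture(scope="session")
def straight_geometry():
    """5 mm straight interface in a 6×4 mm tissue, 1 mm IM band."""
    return make_geometry(InterfaceSpec(5.0, "straight", 0.0, (6.0, 4.0)))


@pytest.fixture(scope="session")
def sinus_geometry():
    """5 mm-chord sinusoidal interface, amplitude 0.5 mm."""
    return make_geometry(InterfaceSpec(5.0, "sinusoidal", 0.5, (6.0, 4.0)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def ray_cast_contains(poly, x, y):
    """Even-odd ray-casting point-in-polygon oracle (exterior ring only)."""
    coords = np.asarray(poly.exterior.coords)
    x1, y1 = coords[:-1, 0], coords[:-1, 1]
    x2, y2 = coords[1:, 0], coords[1:, 1]
    inside = np.zeros(np.shape(x), dtype=bool)
    for ax, ay, bx, by in zip(x1, y1, x2, y2):
        cond = (ay > y) != (by > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = ax + (y - ay) * (bx - ax) / (by - ay)
        inside ^= cond & (x < xint)
    return inside
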