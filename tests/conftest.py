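import numpy as np
import pytest

from pcskit.geometry import Geometry
from pcskit.units import get_registry


@pytest.fixture(scope="session")
def registry():
    return get_registry("codata")


@pytest.fixture(scope="session")
def paper_registry():
    return get_registry("paper")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230721)


@pytest.fixture()
def planar_ring5():
    """Five unequal masses on a ring in the xy-plane (planar asymmetric top)."""
    angles = np.linspace(0.0, 2 * np.pi, 5, endpoint=False)
    radii = np.array([1.0, 1.3, 0.8, 1.1, 0.9])
    coords = np.column_stack(
        [radii * np.cos(angles), radii * np.sin(angles), np.zeros(5)]
    )
    masses = [12.0, 14.003074, 15.994915, 1.007825, 12.0]
    return Geometry.from_arrays("ring5", ["C", "N", "O", "H", "C"], coords, masses=masses)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
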