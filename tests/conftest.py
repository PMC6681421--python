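import numpy as np
import pytest

from alfkrig.geometry import Geometry, infer_bonds
from alfkrig.synthetic import DistortionSpec, build_template, central_fragment, distort


@pytest.fixture
def water():
    """Equilibrium-ish water: O at origin, two H at 0.96 A, 104.5 deg."""
    ang = np.radians(104.5)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.96, 0.0, 0.0],
        [0.96 * np.cos(ang), 0.96 * np.sin(ang), 0.0],
    ])
    return Geometry(["O", "H", "H"], coords, name="water")


@pytest.fixture(scope="session")
def aaa():
    """Idealized capped trialanine template with its bond graph."""
    return build_template("AAA")


@pytest.fixture(scope="session")
def aaa_fragment():
    return central_fragment("AAA")


@pytest.fixture(scope="session")
def aaa_frames(aaa):
    """Sixty mildly expensive distorted conformers, shared across tests."""
    g, b = aaa
    return distort(g, b, DistortionSpec(n_frames=60, seed=42))


def random_rotation(seed: int) -> np.ndarray:
    """Uniform random proper rotation (QR-based, seeded)."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
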