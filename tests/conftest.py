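import numpy as np
import pytest

from poregate import AtomGroupSpec, Frame, PoreGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def axis_geometry():
    """A z-aligned cavity cylinder: z in [0, 3] nm, radius 0.8 nm."""
    return PoreGeometry(
        axis_origin=np.zeros(3),
        axis_direction=np.array([0.0, 0.0, 1.0]),
        z_lo=0.0,
        z_hi=3.0,
        radius=0.8,
    )


@pytest.fixture
def tilted_geometry():
    d = np.array([1.0, 2.0, 2.0]) / 3.0
    return PoreGeometry(
        axis_origin=np.array([1.0, -0.5, 2.0]),
        axis_direction=d,
        z_lo=0.0,
        z_hi=3.0,
        radius=0.8,
    )


def make_frame(coords, box=(10.0, 10.0, 10.0), time=0.0):
    return Frame(coords=np.asarray(coords, float), box=np.asarray(box, float), time=time)


def water_group(n, name="w"):
    return AtomGroupSpec(name, np.arange(n), "water_oxygen")


def random_rotation(rng):
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
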