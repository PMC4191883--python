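import numpy as np
import pytest

from statemap.structio import StructureModel
from statemap.defaults import leut_defaults


def pseudo_model(coords, element="C", resname="UNK", atom_name="X",
                 chain="A"):
    """A bare pseudo-atom model for geometric tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return StructureModel(
        serial=np.arange(1, n + 1),
        atom_name=np.array([atom_name] * n),
        res_name=np.array([resname] * n),
        res_id=np.arange(1, n + 1),
        chain_id=np.array([chain] * n),
        element=np.array([element] * n),
        coords=coords,
    )


def fibonacci_sphere(n, radius):
    """Near-uniform points on a sphere (dense atom shells)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([radius * np.sin(phi) * np.cos(theta),
                     radius * np.sin(phi) * np.sin(theta),
                     radius * np.cos(phi)], axis=1)


def random_rotation(rng):
    """Haar-random rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def cfg():
    return leut_defaults()
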