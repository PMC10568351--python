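import numpy as np
import pytest

from twnscreen.io_structures import Frame, WaterMolecule

OH = 0.9572
HOH = np.deg2rad(104.52)


def random_water(mol_id: str, rng: np.random.Generator, frame_id: int = 0,
                 o_xyz=None) -> WaterMolecule:
    """A rigid water with uniformly random position and orientation."""
    if o_xyz is None:
        o_xyz = rng.uniform(-5.0, 5.0, size=3)
    o_xyz = np.asarray(o_xyz, dtype=float)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    a = rng.normal(size=3)
    a -= np.dot(a, u) * u
    a /= np.linalg.norm(a)
    h2 = np.cos(HOH) * u + np.sin(HOH) * a
    return WaterMolecule(
        mol_id=mol_id, frame_id=frame_id,
        o_xyz=o_xyz, h1_xyz=o_xyz + OH * u, h2_xyz=o_xyz + OH * h2,
    )


def random_frame(n_waters: int, rng: np.random.Generator, frame_id: int = 0,
                 extent: float = 6.0, min_sep: float = 1.5) -> Frame:
    """A frame of randomly placed/oriented waters in a cube of given extent.

    Oxygen positions are rejection-sampled to stay ``min_sep`` apart:
    physical frames never contain interpenetrating molecules.
    """
    waters = []
    taken: list[np.ndarray] = []
    for i in range(n_waters):
        w = random_water(f"w{i}", rng, frame_id)
        while True:
            o = rng.uniform(-extent / 2, extent / 2, size=3)
            if not taken or min(
                np.linalg.norm(o - p) for p in taken
            ) >= min_sep:
                break
        taken.append(o)
        shift = o - w.o_xyz
        waters.append(
            WaterMolecule(
                mol_id=w.mol_id, frame_id=frame_id,
                o_xyz=o, h1_xyz=w.h1_xyz + shift, h2_xyz=w.h2_xyz + shift,
            )
        )
    return Frame(frame_id=frame_id, waters=waters)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_water(w: WaterMolecule, R: np.ndarray, t: np.ndarray) -> WaterMolecule:
    return WaterMolecule(
        mol_id=w.mol_id, frame_id=w.frame_id,
        o_xyz=R @ w.o_xyz + t, h1_xyz=R @ w.h1_xyz + t, h2_xyz=R @ w.h2_xyz + t,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
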