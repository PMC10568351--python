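"""Seeded synthetic fixtures: planted water rings, noise waters, fragments.

The generator emulates what a restrained-protein explicit-water simulation
hands to the analysis: snapshots in a fixed lab frame containing recurrent
4-membered water rings at fixed sites (square geometry, O-O edge ~2.8 Å,
donor hydrogens aimed at the next ring oxygen so every consecutive pair sits
deep in the hydrogen-bond energy well) with small positional jitter, plus
uniformly placed noise waters with random orientations. It is not a physical
water model: there are no dynamics and no thermodynamics, only geometry
constructed to satisfy the pair-energy criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_structures import Frame, FragmentPose, WaterMolecule
from .twn_group import GroupedTWN, ring_plane

OH_BOND = 0.9572  # Å, rigid TIP3P O-H bond
HOH_ANGLE = np.deg2rad(104.52)


@dataclass
class PlantedSite:
    """A recurring square water-ring site.

    ``ring_radius`` is the center-to-corner (half-diagonal) distance; the
    default 1.98 Å gives an O-O edge of ~2.8 Å. ``occupancy_prob`` is the
    per-frame probability that the ring is present.
    """

    center: np.ndarray
    ring_radius: float = 1.98
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    jitter_sigma: float = 0.0
    occupancy_prob: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        if not 0.0 <= self.occupancy_prob <= 1.0:
            raise ValueError("occupancy_prob must be in [0, 1]")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")

    def corner_positions(self) -> np.ndarray:
        """Ideal (jitter-free) O positions: square corners in the ring plane."""
        u, v = _plane_basis(self.normal)
        corners = []
        for k in range(4):
            ang = np.pi / 2.0 * k
            corners.append(
                self.center
                + self.ring_radius * (np.cos(ang) * u + np.sin(ang) * v)
            )
        return np.array(corners)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def _water_with_donor(
    mol_id: str,
    frame_id: int,
    o_xyz: np.ndarray,
    donor_target: np.ndarray,
    ring_normal: np.ndarray,
) -> WaterMolecule:
    """Rigid water at ``o_xyz`` with H1 aimed at ``donor_target``.

    H2 lies in the ring plane at the HOH angle from H1, tilted outward
    (the orientation that puts consecutive ring pairs ~-6 kcal/mol while
    keeping diagonal pairs above the hydrogen-bond threshold).
    """
    u = donor_target - o_xyz
    u /= np.linalg.norm(u)
    a = ring_normal - np.dot(ring_normal, u) * u
    norm = np.linalg.norm(a)
    if norm < 1e-9:  # donor axis parallel to the normal; pick any ⟂
        a = _plane_basis(u)[0]
    else:
        a /= norm
    w = np.cross(u, a)  # in-plane, outward for CCW corner winding
    h2_dir = np.cos(HOH_ANGLE) * u + np.sin(HOH_ANGLE) * w
    return WaterMolecule(
        mol_id=mol_id,
        frame_id=frame_id,
        o_xyz=o_xyz,
        h1_xyz=o_xyz + OH_BOND * u,
        h2_xyz=o_xyz + OH_BOND * h2_dir,
    )


def make_ring_waters(
    site: PlantedSite, rng_seed: int | np.random.Generator, frame_id: int = 0,
    prefix: str = "R",
) -> list[WaterMolecule]:
    """Four waters forming a hydrogen-bonded square ring at the site.

    Each O sits at a (jittered) square corner; water k donates its first
    hydrogen toward the next corner's jittered O, so at zero jitter all four
    consecutive pair energies lie below the hydrogen-bond threshold.
    """
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed
    corners = site.corner_positions()
    if site.jitter_sigma > 0:
        corners = corners + rng.normal(0.0, site.jitter_sigma, size=(4, 3))
    waters = []
    for k in range(4):
        waters.append(
            _water_with_donor(
                mol_id=f"{prefix}{k}",
                frame_id=frame_id,
                o_xyz=corners[k],
                donor_target=corners[(k + 1) % 4],
                ring_normal=site.normal,
            )
        )
    return waters


def _random_water(
    mol_id: str, frame_id: int, o_xyz: np.ndarray, rng: np.random.Generator
) -> WaterMolecule:
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return _water_with_donor(mol_id, frame_id, o_xyz, o_xyz + u, rng.normal(size=3))


def make_frames(
    sites,
    n_frames: int,
    n_noise_waters: int = 0,
    box=(30.0, 30.0, 30.0),
    rng_seed: int = 0,
) -> list[Frame]:
    """Deterministic snapshots with planted rings plus uniform noise waters.

    Each frame contains each site's ring with probability
    ``occupancy_prob``, then ``n_noise_waters`` uniformly placed waters in a
    box of the given edge lengths centered on the mean site center; noise
    oxygens are rejected within 4 Å of any planted corner position so noise
    rarely forms competing rings.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(rng_seed)
    sites = list(sites)
    box = np.asarray(box, dtype=float)
    box_center = (
        np.mean([s.center for s in sites], axis=0) if sites else np.zeros(3)
    )
    planted = (
        np.concatenate([s.corner_positions() for s in sites])
        if sites
        else np.empty((0, 3))
    )
    frames = []
    for f in range(n_frames):
        waters: list[WaterMolecule] = []
        for si, site in enumerate(sites):
            present = site.occupancy_prob >= 1.0 or rng.random() < site.occupancy_prob
            if present:
                waters.extend(
                    make_ring_waters(site, rng, frame_id=f, prefix=f"S{si}W")
                )
        k = 0
        while k < n_noise_waters:
            o = box_center + (rng.random(3) - 0.5) * box
            if planted.size and np.min(np.linalg.norm(planted - o, axis=1)) < 4.0:
                continue
            waters.append(_random_water(f"N{k}", f, o, rng))
            k += 1
        frames.append(Frame(frame_id=f, waters=waters, box=box.copy()))
    return frames


def make_fragment_at(
    group_or_point,
    offset=(0.0, 0.0, 0.0),
    n_atoms: int = 4,
    rng_seed: int = 0,
    element: str = "C",
    frag_id: str = "frag",
) -> FragmentPose:
    """A pseudo-fragment whose centroid sits at the target plus ``offset``.

    Given a grouped site and ``n_atoms == 4`` the atoms go exactly on the
    four cluster centroids (shifted by ``offset``), reproducing the on-site
    pass case; otherwise atoms are scattered in a ~2 Å disc matching the
    ring footprint. Large offsets yield decoys.
    """
    rng = np.random.default_rng(rng_seed)
    offset = np.asarray(offset, dtype=float)
    if isinstance(group_or_point, GroupedTWN):
        centroids = np.asarray(group_or_point.centroids, dtype=float)
        center = centroids.mean(axis=0)
        normal, _ = ring_plane(centroids)
        if n_atoms == 4:
            coords = centroids + offset
            return FragmentPose(
                frag_id=frag_id,
                atoms=[(element, xyz) for xyz in coords],
                source="synthetic",
            )
    else:
        center = np.asarray(group_or_point, dtype=float)
        normal = np.array([0.0, 0.0, 1.0])
    u, v = _plane_basis(normal)
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    pts = []
    for _ in range(n_atoms):
        r = 2.0 * np.sqrt(rng.random())
        ang = 2.0 * np.pi * rng.random()
        pts.append(r * np.cos(ang) * u + r * np.sin(ang) * v)
    pts = np.array(pts)
    pts = pts - pts.mean(axis=0) + center + offset
    return FragmentPose(
        frag_id=frag_id,
        atoms=[(element, xyz) for xyz in pts],
        source="synthetic",
    )


def default_demo_sites() -> list[PlantedSite]:
    """Five well-separated planted sites inside a 20 Å analysis sphere."""
    centers = [
        (0.0, 0.0, 0.0),
        (6.0, 0.0, 0.0),
        (0.0, 6.5, 0.0),
        (-5.0, -3.0, 4.0),
        (3.0, -5.0, -4.5),
    ]
    normals = [
        (0.0, 0.0, 1.0),
        (0.0, 1.0, 1.0),
        (1.0, 0.0, 1.0),
        (1.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    ]
    return [
        PlantedSite(center=np.array(c), normal=np.array(n), jitter_sigma=0.1)
        for c, n in zip(centers, normals)
    ]
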