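"""Hydrogen-bond graph construction and 4-membered water-ring detection.

The pair interaction energy between two rigid three-site (TIP3P) waters is

    v(a, b) = sum_{i on a} sum_{j on b} q_i q_j e^2 / r_ij
              + A / r_OO^12 - C / r_OO^6

i.e. nine Coulomb site-site terms plus one O-O Lennard-Jones term. A pair is
hydrogen-bonded when v <= -2.25 kcal/mol (the minimum of the pair-energy
distribution). A ring is any simple 4-cycle of the resulting per-frame
hydrogen-bond graph; planar and non-planar rings are both kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .io_structures import Frame, SiteDefinition, WaterMolecule


class DegenerateGeometryError(ValueError):
    """Molecular geometry too degenerate to evaluate (overlapping sites)."""


@dataclass(frozen=True)
class EnergyParameters:
    """TIP3P pair-potential parameters (kcal, Å, elementary charges).

    ``k_e2`` is the Coulomb conversion factor e² in kcal·Å·mol⁻¹·e⁻²
    (CHARMM convention). ``hbond_threshold`` is the pair-energy criterion
    below which two waters count as hydrogen-bonded; ``cutoff`` is the O–O
    neighbor-list distance beyond which the pair energy provably cannot
    reach the threshold (orientation-optimised TIP3P pairs dip below
    −2.25 kcal·mol⁻¹ out to ≈4.1 Å O–O, hence the 4.25 Å default).
    """

    q_O: float = -0.834
    q_H: float = 0.417
    A: float = 582000.0
    C: float = 595.0
    k_e2: float = 332.0636
    hbond_threshold: float = -2.25
    cutoff: float = 4.25

    def __post_init__(self) -> None:
        if abs(2 * self.q_H + self.q_O) > 1e-9:
            raise ValueError("water must be neutral: 2*q_H + q_O == 0")
        if self.A <= 0 or self.C <= 0:
            raise ValueError("LJ coefficients must be positive")
        if self.hbond_threshold >= 0:
            raise ValueError("hbond_threshold must be negative")


@dataclass(frozen=True)
class TWNRing:
    """A 4-membered cyclic water network from a single frame.

    ``members`` is the canonically ordered cycle of water ids;
    ``o_coords`` are the four O positions in member order (Å).
    """

    ring_id: str
    frame_id: int
    members: tuple[str, str, str, str]
    o_coords: np.ndarray

    def centroid(self) -> np.ndarray:
        return np.asarray(self.o_coords, dtype=float).mean(axis=0)


def _sites(w: WaterMolecule, params: EnergyParameters):
    coords = np.array([w.o_xyz, w.h1_xyz, w.h2_xyz], dtype=float)
    charges = np.array([params.q_O, params.q_H, params.q_H])
    return coords, charges


def pair_interaction_energy(
    a: WaterMolecule, b: WaterMolecule, params: EnergyParameters = EnergyParameters()
) -> float:
    """Pair potential v(a, b) in kcal/mol; symmetric in its arguments."""
    r_oo = float(np.linalg.norm(np.asarray(a.o_xyz) - np.asarray(b.o_xyz)))
    if r_oo < 0.1:
        raise DegenerateGeometryError(
            f"overlapping waters: O-O distance {r_oo:.3f} Å"
        )
    ca, qa = _sites(a, params)
    cb, qb = _sites(b, params)
    rij = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    coulomb = params.k_e2 * float(np.sum(qa[:, None] * qb[None, :] / rij))
    lj = params.A / r_oo**12 - params.C / r_oo**6
    return coulomb + lj


def build_hbond_graph(
    frame: Frame,
    params: EnergyParameters = EnergyParameters(),
    cutoff: float | None = None,
) -> nx.Graph:
    """Per-frame hydrogen-bond graph.

    Nodes are water mol_ids; an undirected edge carries the pair energy and
    exists iff v(a, b) <= ``params.hbond_threshold`` (inclusive). Pairs with
    O-O distance beyond ``cutoff`` are skipped without energy evaluation.
    """
    if cutoff is None:
        cutoff = params.cutoff
    g = nx.Graph(frame_id=frame.frame_id)
    waters = frame.waters
    g.add_nodes_from(w.mol_id for w in waters)
    if len(waters) < 2:
        return g
    o = np.array([w.o_xyz for w in waters])
    tree = cKDTree(o)
    for i, j in tree.query_pairs(cutoff):
        v = pair_interaction_energy(waters[i], waters[j], params)
        if v <= params.hbond_threshold:
            g.add_edge(waters[i].mol_id, waters[j].mol_id, energy=v)
    return g


def canonical_ring_order(members: tuple) -> tuple:
    """Unique representative of a 4-cycle under rotation and reflection.

    Starts at the smallest member id; the second element is the smaller of
    that member's two cycle neighbors.
    """
    m = list(members)
    start = m.index(min(m))
    m = m[start:] + m[:start]
    if m[3] < m[1]:
        m = [m[0], m[3], m[2], m[1]]
    return tuple(m)


def enumerate_4rings(graph: nx.Graph, frame: Frame) -> list[TWNRing]:
    """Every simple 4-cycle of the frame's hydrogen-bond graph.

    Each 4-water set appears once, in canonical cyclic order; chords are
    permitted (a K4 subgraph yields three distinct rings) and no planarity
    filter is applied.
    """
    coords = {w.mol_id: np.asarray(w.o_xyz, dtype=float) for w in frame.waters}
    rings: list[TWNRing] = []
    seen: set[tuple] = set()
    for cycle in nx.simple_cycles(graph, length_bound=4):
        if len(cycle) != 4:
            continue
        members = canonical_ring_order(tuple(cycle))
        if members in seen:
            continue
        seen.add(members)
        rings.append(
            TWNRing(
                ring_id=f"f{frame.frame_id}:" + "|".join(map(str, members)),
                frame_id=frame.frame_id,
                members=members,
                o_coords=np.array([coords[m] for m in members]),
            )
        )
    rings.sort(key=lambda r: r.ring_id)
    return rings


def detect_rings(
    frames,
    params: EnergyParameters = EnergyParameters(),
    cutoff: float | None = None,
) -> list[TWNRing]:
    """Convenience: hydrogen-bond graph + ring enumeration over many frames."""
    rings: list[TWNRing] = []
    for frame in frames:
        g = build_hbond_graph(frame, params, cutoff)
        rings.extend(enumerate_4rings(g, frame))
    return rings


def filter_site(rings, site: SiteDefinition) -> list[TWNRing]:
    """Keep rings whose O centroid lies within the site sphere (inclusive)."""
    return [
        r
        for r in rings
        if np.linalg.norm(r.centroid() - site.center_xyz) <= site.radius
    ]


def site_center_from_residues(
    protein_pdb: str | Path,
    residue_selection,
    radius: float = 20.0,
) -> SiteDefinition:
    """Site center from the mean Cα position of selected protein residues.

    ``residue_selection`` is an iterable of ``(chain_id, res_id)`` pairs.
    Falls back to all atoms of the selection when no Cα is present.
    """
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(str(protein_pdb)).get_structure(model=1)
    mask = np.zeros(atoms.array_length(), dtype=bool)
    for chain, res_id in residue_selection:
        mask |= (atoms.chain_id == str(chain)) & (atoms.res_id == int(res_id))
    if not mask.any():
        avail = sorted(
            {(c, int(r)) for c, r in zip(atoms.chain_id, atoms.res_id)}
        )
        raise ValueError(
            f"selection matched no residues; available: {avail[:50]}"
        )
    sel = atoms[mask]
    ca = sel[sel.atom_name == "CA"]
    use = ca if ca.array_length() > 0 else sel
    return SiteDefinition(center_xyz=use.coord.mean(axis=0), radius=radius)
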