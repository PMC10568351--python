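"""Structure file I/O: water frames, fragment poses, grouped-network output.

Water frames are plain PDB files — either one file per MD snapshot or a
single multi-MODEL file. Coordinates are taken as-is in a single lab frame:
no alignment or periodic wrapping is applied (frames from a
protein-restrained simulation are already co-registered; users of
unrestrained trajectories must pre-align).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

#: residue names recognised as explicit water
WATER_RESNAMES = ("HOH", "SOL", "WAT", "TIP3")


class EmptyInputError(ValueError):
    """No usable records were parsed from an input file."""


@dataclass(frozen=True)
class WaterMolecule:
    """One explicit three-site water molecule.

    ``o_xyz``/``h1_xyz``/``h2_xyz`` are lab-frame coordinates in Å.
    """

    mol_id: str
    frame_id: int
    o_xyz: np.ndarray
    h1_xyz: np.ndarray
    h2_xyz: np.ndarray

    def __post_init__(self) -> None:
        for name in ("o_xyz", "h1_xyz", "h2_xyz"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )

    def oh_distances(self) -> tuple[float, float]:
        return (
            float(np.linalg.norm(self.h1_xyz - self.o_xyz)),
            float(np.linalg.norm(self.h2_xyz - self.o_xyz)),
        )


@dataclass
class Frame:
    """All waters of one MD snapshot (plus the periodic box, if known)."""

    frame_id: int
    waters: list[WaterMolecule]
    box: np.ndarray | None = None


@dataclass
class FragmentPose:
    """A docked fragment pose: element symbols and 3D coordinates.

    Hydrogens are retained but flagged; scoring uses heavy atoms only.
    """

    frag_id: str
    atoms: list[tuple[str, np.ndarray]]
    source: str = ""

    def heavy_atoms(self) -> list[tuple[str, np.ndarray]]:
        return [(el, xyz) for el, xyz in self.atoms if el.upper() != "H"]

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_atoms())


@dataclass
class SiteDefinition:
    """A spherical binding-site region (center + radius, Å)."""

    center_xyz: np.ndarray
    radius: float = 20.0

    def __post_init__(self) -> None:
        self.center_xyz = np.asarray(self.center_xyz, dtype=float)
        if self.radius <= 0:
            raise ValueError("site radius must be positive")


# ---------------------------------------------------------------------------
# water frame reading / writing
# ---------------------------------------------------------------------------

def _waters_from_atom_array(
    atoms: struc.AtomArray,
    frame_id: int,
    resnames: Sequence[str],
    drop_log: list[str],
) -> list[WaterMolecule]:
    mask = np.isin(atoms.res_name, resnames)
    sel = atoms[mask]
    waters: list[WaterMolecule] = []
    if sel.array_length() == 0:
        return waters
    # group records by (chain, residue id): one water per residue
    keys = list(zip(sel.chain_id, sel.res_id))
    order: dict[tuple, list[int]] = {}
    for idx, key in enumerate(keys):
        order.setdefault(key, []).append(idx)
    for (chain, res_id), idxs in order.items():
        sub = sel[idxs]
        o_idx = np.where(sub.element == "O")[0]
        h_idx = np.where(sub.element == "H")[0]
        mol_id = f"{chain}:{res_id}".strip()
        if len(o_idx) != 1 or len(h_idx) < 2:
            drop_log.append(
                f"frame {frame_id} residue {mol_id}: "
                f"{len(o_idx)} O / {len(h_idx)} H records"
            )
            continue
        waters.append(
            WaterMolecule(
                mol_id=mol_id,
                frame_id=frame_id,
                o_xyz=sub.coord[o_idx[0]],
                h1_xyz=sub.coord[h_idx[0]],
                h2_xyz=sub.coord[h_idx[1]],
            )
        )
    return waters


def read_water_frames(
    path_or_dir: str | Path,
    format_hint: str | None = None,
    resnames: Sequence[str] = WATER_RESNAMES,
) -> list[Frame]:
    """Read explicit-water snapshots from PDB input.

    Parameters
    ----------
    path_or_dir
        A multi-MODEL PDB file (``format_hint="pdb_models"``), or a
        directory of per-snapshot PDB files (``"pdb_files"``, lexicographic
        order). The hint is inferred from the path type when omitted.
    resnames
        Residue names accepted as water.

    Returns
    -------
    list of :class:`Frame`, ``frame_id`` assigned in encounter order from 0.
    Waters with missing hydrogens are skipped with a logged warning.
    """
    path = Path(path_or_dir)
    if format_hint is None:
        format_hint = "pdb_files" if path.is_dir() else "pdb_models"
    if format_hint == "pdb_files":
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".pdb")
        if not files:
            raise EmptyInputError(f"no PDB files found in {path}")
    elif format_hint == "pdb_models":
        files = [path]
    else:
        raise ValueError(f"unknown format_hint {format_hint!r}")

    frames: list[Frame] = []
    drop_log: list[str] = []
    frame_id = 0
    for f in files:
        if not f.exists():
            raise IOError(f"cannot read water frames: {f} does not exist")
        pdb = PDBFile.read(str(f))
        n_models = pdb.get_model_count()
        for m in range(1, n_models + 1):
            atoms = pdb.get_structure(model=m)
            box = None
            if atoms.box is not None:
                box = np.diagonal(np.asarray(atoms.box, dtype=float)).copy()
            waters = _waters_from_atom_array(atoms, frame_id, resnames, drop_log)
            frames.append(Frame(frame_id=frame_id, waters=waters, box=box))
            frame_id += 1
    if drop_log:
        logger.warning(
            "skipped %d incomplete water(s): %s", len(drop_log), "; ".join(drop_log)
        )
    if sum(len(fr.waters) for fr in frames) == 0:
        raise EmptyInputError(f"no waters parsed from {path}")
    return frames


def _frame_to_atom_array(frame: Frame, resname: str = "HOH") -> struc.AtomArray:
    n = 3 * len(frame.waters)
    arr = struc.AtomArray(n)
    coords = np.empty((n, 3))
    for i, w in enumerate(frame.waters):
        coords[3 * i] = w.o_xyz
        coords[3 * i + 1] = w.h1_xyz
        coords[3 * i + 2] = w.h2_xyz
    arr.coord = coords
    arr.chain_id[:] = "W"
    arr.res_id[:] = np.repeat(np.arange(1, len(frame.waters) + 1), 3)
    arr.res_name[:] = resname
    arr.atom_name[:] = np.tile(["O", "H1", "H2"], len(frame.waters))
    arr.element[:] = np.tile(["O", "H", "H"], len(frame.waters))
    arr.hetero[:] = True
    return arr


def write_water_frames(frames: Iterable[Frame], path: str | Path) -> None:
    """Write frames as a multi-MODEL PDB (inverse of :func:`read_water_frames`)."""
    path = Path(path)
    lines: list[str] = []
    for frame in frames:
        pdbf = PDBFile()
        pdbf.set_structure(_frame_to_atom_array(frame))
        atom_lines = [
            ln for ln in pdbf.lines if ln.startswith(("ATOM", "HETATM"))
        ]
        lines.append(f"MODEL     {frame.frame_id + 1:>4d}")
        lines.extend(atom_lines)
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fragment reading / writing
# ---------------------------------------------------------------------------

def read_fragments(path: str | Path) -> list[FragmentPose]:
    """Read fragment poses from a multi-record SDF or a PDB file.

    Records without 3D coordinates raise a per-record warning but parsing of
    the remaining records continues; apparently-2D records (all z == 0) are
    retained with a warning.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read fragments: {path} does not exist")
    poses: list[FragmentPose] = []
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                warnings.warn(f"{path} record {i}: unparseable, skipped")
                continue
            if mol.GetNumConformers() == 0:
                warnings.warn(f"{path} record {i}: no coordinates, skipped")
                continue
            conf = mol.GetConformer()
            if not conf.Is3D():
                warnings.warn(f"{path} record {i}: 2D coordinates; retained")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            frag_id = name or f"frag{i}"
            atoms = [
                (mol.GetAtomWithIdx(j).GetSymbol(),
                 np.array(conf.GetAtomPosition(j)))
                for j in range(mol.GetNumAtoms())
            ]
            poses.append(FragmentPose(frag_id=frag_id, atoms=atoms,
                                      source=f"{path}#{i}"))
    else:
        mol = Chem.MolFromPDBFile(str(path), removeHs=False, sanitize=False)
        if mol is None or mol.GetNumConformers() == 0:
            raise EmptyInputError(f"no 3D structure parsed from {path}")
        conf = mol.GetConformer()
        atoms = [
            (mol.GetAtomWithIdx(j).GetSymbol(), np.array(conf.GetAtomPosition(j)))
            for j in range(mol.GetNumAtoms())
        ]
        poses.append(FragmentPose(frag_id=path.stem, atoms=atoms, source=str(path)))
    if not poses:
        raise EmptyInputError(f"no fragments parsed from {path}")
    return poses


def write_fragments_sdf(fragments: Iterable[FragmentPose], path: str | Path) -> None:
    """Write fragment poses as a multi-record SDF (coordinates + elements only)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    try:
        for frag in fragments:
            mol = Chem.RWMol()
            conf = Chem.Conformer(len(frag.atoms))
            for j, (el, xyz) in enumerate(frag.atoms):
                mol.AddAtom(Chem.Atom(el))
                conf.SetAtomPosition(j, Point3D(*map(float, xyz)))
            mol.AddConformer(conf)
            mol.SetProp("_Name", frag.frag_id)
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# grouped-network output
# ---------------------------------------------------------------------------

def write_grouped_twn_pdb(groups: Sequence, path: str | Path) -> None:
    """Write grouped water networks as an oxygen-only pseudo-atom PDB.

    One residue per group (residue name ``TWN``) holding every member ring's
    O atoms, plus the four cluster centroids as a separate residue (``TWC``).
    The occupancy column stores group size normalised by the largest group.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("no groups to write")
    max_size = max(len(g.member_rings) for g in groups)
    n_atoms = sum(4 * len(g.member_rings) + 4 for g in groups)
    arr = struc.AtomArray(n_atoms)
    arr.add_annotation("occupancy", dtype=float)
    coords = np.empty((n_atoms, 3))
    k = 0
    res_id = 0
    for g in groups:
        occ = len(g.member_rings) / max_size
        res_id += 1
        for ring in g.member_rings:
            for xyz in ring.o_coords:
                coords[k] = xyz
                arr.res_id[k] = res_id
                arr.res_name[k] = "TWN"
                arr.occupancy[k] = occ
                k += 1
        res_id += 1
        for xyz in g.centroids:
            coords[k] = xyz
            arr.res_id[k] = res_id
            arr.res_name[k] = "TWC"
            arr.occupancy[k] = occ
            k += 1
    arr.coord = coords
    arr.chain_id[:] = "G"
    arr.atom_name[:] = "O"
    arr.element[:] = "O"
    arr.hetero[:] = True
    pdbf = PDBFile()
    pdbf.set_structure(arr)
    pdbf.write(str(path))


def read_grouped_twn_centroids(path: str | Path) -> list[np.ndarray]:
    """Read back the centroid records (residue ``TWC``) of a grouped-network PDB.

    Returns one (4, 3) array per group, in file order.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    sel = atoms[atoms.res_name == "TWC"]
    out = []
    for rid in np.unique(sel.res_id):
        out.append(np.asarray(sel.coord[sel.res_id == rid], dtype=float))
    return out


# ---------------------------------------------------------------------------
# tabular / JSON results
# ---------------------------------------------------------------------------

def write_screen_table(records: Sequence, path: str | Path) -> None:
    """Write per-(fragment, group) screening scores as CSV."""
    import pandas as pd

    rows = [
        {
            "frag_id": r.frag_id,
            "group_id": r.group_id,
            "shape_similarity": r.shape_similarity,
            "avg_distance": r.avg_distance,
            "passed": r.passed,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=["frag_id", "group_id", "shape_similarity", "avg_distance", "passed"],
    )
    df.to_csv(path, index=False)


def write_group_sidecar(groups: Sequence, n_frames: int | None, path: str | Path) -> None:
    """Write a JSON sidecar describing grouped networks (centroids, planes)."""
    payload = {
        "n_frames": n_frames,
        "groups": [
            {
                "group_id": g.group_id,
                "n_members": len(g.member_rings),
                "occupancy": g.occupancy,
                "centroids": np.asarray(g.centroids).tolist(),
                "planes": [
                    {"normal": np.asarray(n).tolist(), "point": np.asarray(p).tolist()}
                    for n, p in g.planes
                ],
            }
            for g in groups
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_group_sidecar(path: str | Path):
    """Load grouped networks from a JSON sidecar (inverse of the writer).

    Member rings are not stored in the sidecar, so the returned objects carry
    an empty ring list; centroids, planes and occupancy are preserved.
    """
    from .twn_group import GroupedTWN

    data = json.loads(Path(path).read_text())
    groups = []
    for g in data["groups"]:
        groups.append(
            GroupedTWN(
                group_id=g["group_id"],
                member_rings=[],
                centroids=np.asarray(g["centroids"], dtype=float),
                planes=[
                    (np.asarray(p["normal"], dtype=float),
                     np.asarray(p["point"], dtype=float))
                    for p in g["planes"]
                ],
                occupancy=g["occupancy"],
                n_members=g["n_members"],
            )
        )
    return groups, data.get("n_frames")
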