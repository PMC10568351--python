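"""Two-stage spatial grouping of recurrent water rings across frames.

Primary grouping registers every ring O atom on a 0.5 Å grid and links two
rings when their four O atoms can be matched one-to-one within each other's
extended zones (the 3x3x3 cell neighborhood); groups are the connected
components of that relation. DBSCAN then locates the center of each of the
four O-atom clusters, and secondary grouping merges primary groups whose
four centers can be matched pairwise within 1 Å. The result is a set of
"grouped TWNs": recurrent ring sites summarised by four cluster centroids
plus one best-fit plane per member ring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .twn_detect import DegenerateGeometryError, TWNRing

_BIG = 1.0e6  # assignment cost for cell-forbidden pairings


@dataclass
class GridIndex:
    """Half-open cubic grid over ring O atoms.

    ``cells`` maps an integer cell triple to the ``(ring_index, o_index)``
    pairs registered there; the cell of point p is
    ``floor((p - origin) / spacing)`` componentwise.
    """

    origin: np.ndarray
    spacing: float
    cells: dict[tuple[int, int, int], list[tuple[int, int]]]

    def cell_of(self, p) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(p, dtype=float) - self.origin) / self.spacing)
        return tuple(int(i) for i in idx)


@dataclass
class PrimaryGroup:
    """A connected component of the primary (grid-zone) link relation."""

    group_id: str
    member_rings: list[TWNRing]
    #: per member ring, cluster index of each of its four O atoms
    assignments: list[np.ndarray]
    o_centers: np.ndarray | None = None

    def o_clusters(self) -> list[np.ndarray]:
        """The four O point sets, one point per member ring each."""
        sets: list[list[np.ndarray]] = [[], [], [], []]
        for ring, assign in zip(self.member_rings, self.assignments):
            for o_idx, c in enumerate(assign):
                sets[c].append(np.asarray(ring.o_coords[o_idx], dtype=float))
        return [np.array(s) for s in sets]


@dataclass
class GroupedTWN:
    """A final grouped water-ring site.

    ``centroids`` are the four DBSCAN cluster centers (lexicographically
    ordered); ``planes`` holds one total-least-squares plane per member ring
    as ``(unit normal, point)``. ``occupancy`` is member count over total
    frames when the frame count is known.
    """

    group_id: str
    member_rings: list[TWNRing]
    centroids: np.ndarray
    planes: list[tuple[np.ndarray, np.ndarray]]
    occupancy: float | None = None
    n_members: int | None = None

    def __post_init__(self) -> None:
        if self.n_members is None:
            self.n_members = len(self.member_rings)


def build_grid(rings: list[TWNRing], spacing: float = 0.5) -> GridIndex:
    """Register every ring O atom in a cubic grid.

    The origin is the componentwise minimum of all O coordinates snapped
    down to a multiple of the spacing, so identical inputs always land in
    identical cells; the extended-zone linkage keeps the partition robust to
    the (arbitrary) origin choice.
    """
    if not rings:
        raise ValueError("no rings to grid")
    all_o = np.concatenate([np.asarray(r.o_coords, dtype=float) for r in rings])
    origin = np.floor(all_o.min(axis=0) / spacing) * spacing
    grid = GridIndex(origin=origin, spacing=spacing, cells={})
    for ri, ring in enumerate(rings):
        for oi in range(4):
            grid.cells.setdefault(grid.cell_of(ring.o_coords[oi]), []).append(
                (ri, oi)
            )
    return grid


def _match_rings(
    coords_a: np.ndarray, coords_b: np.ndarray,
    cells_a: np.ndarray, cells_b: np.ndarray,
):
    """Min-cost O-atom correspondence constrained to the extended zones.

    Returns (row, col) index arrays, or None when no one-to-one matching
    keeps every pair within +/-1 cell on every axis.
    """
    allowed = (
        np.abs(cells_a[:, None, :] - cells_b[None, :, :]).max(axis=-1) <= 1
    )
    if not allowed.any(axis=1).all() or not allowed.any(axis=0).all():
        return None
    dist = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=-1)
    cost = np.where(allowed, dist, _BIG)
    row, col = linear_sum_assignment(cost)
    if not allowed[row, col].all():
        return None
    return row, col


def primary_grouping(
    rings: list[TWNRing], grid: GridIndex
) -> list[PrimaryGroup]:
    """Connected components of the extended-zone link relation.

    Two rings are directly linked iff their four O atoms admit a one-to-one
    correspondence with every matched pair inside each other's 3x3x3 cell
    neighborhood; the minimum-distance feasible assignment fixes which O
    belongs to which cluster, propagated over a spanning tree so every member
    ring contributes exactly one O atom to each of the four clusters.
    """
    order = sorted(range(len(rings)), key=lambda i: rings[i].ring_id)
    coords = [np.asarray(rings[i].o_coords, dtype=float) for i in order]
    cells = [
        np.array([grid.cell_of(c[k]) for k in range(4)], dtype=int)
        for c in coords
    ]
    centroids = np.array([c.mean(axis=0) for c in coords])
    n = len(order)
    link = nx.Graph()
    link.add_nodes_from(range(n))
    if n > 1:
        # matched O pairs differ by <= 2*spacing per axis, bounding the
        # centroid separation of linkable rings
        reach = 2.0 * grid.spacing * np.sqrt(3.0) + 1e-9
        tree = cKDTree(centroids)
        pairs = sorted(tree.query_pairs(reach))
        uf = {i: i for i in range(n)}

        def find(x):
            while uf[x] != x:
                uf[x] = uf[uf[x]]
                x = uf[x]
            return x

        for a, b in pairs:
            if find(a) == find(b):
                continue  # already transitively linked; no new edge needed
            m = _match_rings(coords[a], coords[b], cells[a], cells[b])
            if m is not None:
                link.add_edge(a, b, match=m)
                uf[find(a)] = find(b)

    groups: list[PrimaryGroup] = []
    for comp in nx.connected_components(link):
        root = min(comp)
        assign = {root: np.arange(4)}
        for a, b in nx.bfs_edges(link, root):
            row, col = link.edges[a, b]["match"]
            new = np.empty(4, dtype=int)
            new[col] = assign[a][row]
            assign[b] = new
        members = sorted(comp)
        groups.append(
            PrimaryGroup(
                group_id=f"p{len(groups)}",
                member_rings=[rings[order[i]] for i in members],
                assignments=[assign[i] for i in members],
            )
        )
    groups.sort(key=lambda g: g.member_rings[0].ring_id)
    for i, g in enumerate(groups):
        g.group_id = f"p{i}"
    return groups


def _dbscan_center(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    points = np.atleast_2d(points)
    if len(points) == 1:
        return points[0].copy()
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit(points).labels_
    good = labels[labels >= 0]
    if good.size == 0:
        warnings.warn("DBSCAN labelled all points noise; using plain mean")
        return points.mean(axis=0)
    counts = np.bincount(good)
    return points[labels == counts.argmax()].mean(axis=0)


def cluster_centers(
    group: PrimaryGroup, eps: float = 1.0, min_samples: int = 1
) -> np.ndarray:
    """DBSCAN center of each of the group's four O clusters.

    The center is the mean of the largest DBSCAN cluster; when every point
    is labelled noise the plain mean is used and a warning recorded. The
    result is cached on the group.
    """
    centers = np.array(
        [_dbscan_center(pts, eps, min_samples) for pts in group.o_clusters()]
    )
    group.o_centers = centers
    return centers


def ring_plane(points) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through four points.

    The normal is the singular vector of the smallest singular value of the
    centered coordinate matrix, with its sign fixed to a positive z
    component (ties: positive y, then x). Raises
    :class:`DegenerateGeometryError` for collinear point sets.
    """
    pts = np.asarray(points, dtype=float)
    p0 = pts.mean(axis=0)
    centered = pts - p0
    _, s, vt = np.linalg.svd(centered)
    scale = max(s[0], 1e-12)
    if s[1] / scale < 1e-8:
        raise DegenerateGeometryError("points are (nearly) collinear")
    n = vt[-1]
    for k in (2, 1, 0):
        if abs(n[k]) > 1e-12:
            if n[k] < 0:
                n = -n
            break
    return n, p0


def _match_centers(ca: np.ndarray, cb: np.ndarray, radius: float):
    dist = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    row, col = linear_sum_assignment(dist)
    if dist[row, col].max() <= radius:
        return row, col
    return None


def secondary_grouping(
    primaries: list[PrimaryGroup],
    radius: float = 1.0,
    eps: float = 1.0,
    min_samples: int = 1,
    n_frames: int | None = None,
) -> list[GroupedTWN]:
    """Merge primary groups whose four cluster centers match within ``radius``.

    Linkage is single-linkage transitive closure over the pairwise
    criterion: a minimum-cost one-to-one assignment of the two center
    quadruples with every matched pair at most ``radius`` apart (inclusive).
    Merged groups pool their O clusters (following the center
    correspondence) and re-derive centroids with DBSCAN; each member ring
    contributes one total-least-squares plane through its own four O atoms.
    """
    for g in primaries:
        if g.o_centers is None:
            cluster_centers(g, eps, min_samples)
    order = sorted(range(len(primaries)),
                   key=lambda i: primaries[i].member_rings[0].ring_id)
    n = len(order)
    link = nx.Graph()
    link.add_nodes_from(range(n))
    for a in range(n):
        for b in range(a + 1, n):
            m = _match_centers(
                primaries[order[a]].o_centers, primaries[order[b]].o_centers, radius
            )
            if m is not None:
                link.add_edge(a, b, match=m)

    groups: list[GroupedTWN] = []
    for comp in nx.connected_components(link):
        root = min(comp)
        # propagate the cluster correspondence over a spanning tree
        perm = {root: np.arange(4)}
        for a, b in nx.bfs_edges(link, root):
            row, col = link.edges[a, b]["match"]
            new = np.empty(4, dtype=int)
            new[col] = perm[a][row]
            perm[b] = new
        pooled: list[list[np.ndarray]] = [[], [], [], []]
        rings: list[TWNRing] = []
        for i in sorted(comp):
            prim = primaries[order[i]]
            clusters = prim.o_clusters()
            for c in range(4):
                pooled[perm[i][c]].append(clusters[c])
            rings.extend(prim.member_rings)
        centroids = np.array(
            [_dbscan_center(np.concatenate(p), eps, min_samples) for p in pooled]
        )
        # canonical centroid order for run-to-run reproducibility
        centroids = centroids[np.lexsort(centroids.T[::-1])]
        rings.sort(key=lambda r: r.ring_id)
        planes = [ring_plane(r.o_coords) for r in rings]
        occ = len(rings) / n_frames if n_frames else None
        groups.append(
            GroupedTWN(
                group_id=f"g{len(groups)}",
                member_rings=rings,
                centroids=centroids,
                planes=planes,
                occupancy=occ,
            )
        )
    groups.sort(key=lambda g: g.member_rings[0].ring_id)
    for i, g in enumerate(groups):
        g.group_id = f"g{i}"
    return groups


def group_rings(
    rings: list[TWNRing],
    spacing: float = 0.5,
    secondary_radius: float = 1.0,
    eps: float = 1.0,
    min_samples: int = 1,
    n_frames: int | None = None,
) -> list[GroupedTWN]:
    """Full grouping pipeline: grid, primary grouping, secondary grouping."""
    grid = build_grid(rings, spacing)
    primaries = primary_grouping(rings, grid)
    return secondary_grouping(
        primaries, secondary_radius, eps, min_samples, n_frames
    )
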