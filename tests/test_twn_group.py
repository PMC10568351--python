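"""Grid registration, two-stage grouping and plane-fit checks."""

from itertools import permutations

import networkx as nx
import numpy as np
import pytest

from twnscreen.synthetic import PlantedSite, default_demo_sites, make_frames
from twnscreen.twn_detect import DegenerateGeometryError, TWNRing, detect_rings
from twnscreen.twn_group import (
    GroupedTWN,
    build_grid,
    cluster_centers,
    group_rings,
    primary_grouping,
    ring_plane,
    secondary_grouping,
)


def make_ring(ring_id, o_coords, frame_id=0):
    return TWNRing(
        ring_id=ring_id, frame_id=frame_id,
        members=(f"{ring_id}a", f"{ring_id}b", f"{ring_id}c", f"{ring_id}d"),
        o_coords=np.asarray(o_coords, dtype=float),
    )


SQUARE = np.array([[0, 0, 0], [2.8, 0, 0], [2.8, 2.8, 0], [0, 2.8, 0]], float)


def oracle_partition(rings, spacing=0.5):
    """Brute-force primary+transitive partition over all ring pairs.

    Feasibility of a link is tested by trying all 24 O-atom permutations
    against the +/-1-cell criterion — independent of the assignment-based
    implementation.
    """
    grid = build_grid(rings, spacing)
    cells = [
        np.array([grid.cell_of(r.o_coords[k]) for k in range(4)]) for r in rings
    ]
    g = nx.Graph()
    g.add_nodes_from(range(len(rings)))
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            for perm in permutations(range(4)):
                if all(
                    np.abs(cells[i][k] - cells[j][perm[k]]).max() <= 1
                    for k in range(4)
                ):
                    g.add_edge(i, j)
                    break
    return {frozenset(rings[i].ring_id for i in c)
            for c in nx.connected_components(g)}


class TestGrid:
    def test_cell_floor_arithmetic(self):
        ring = make_ring("r", SQUARE)
        grid = build_grid([ring], spacing=0.5)
        assert grid.cell_of(grid.origin + [0.74, 0, 0]) == (1, 0, 0)

    def test_boundary_lower_edge_inclusive(self):
        ring = make_ring("r", SQUARE)
        grid = build_grid([ring], spacing=0.5)
        assert grid.cell_of(grid.origin + [0.5, 0, 0]) == (1, 0, 0)
        assert grid.cell_of(grid.origin) == (0, 0, 0)

    def test_all_o_atoms_registered(self, rng):
        rings = [
            make_ring(f"r{i}", SQUARE + rng.uniform(-5, 5, 3)) for i in range(10)
        ]
        grid = build_grid(rings)
        assert sum(len(v) for v in grid.cells.values()) == 40


class TestPrimaryGrouping:
    def test_identical_rings_grouped(self):
        rings = [make_ring("a", SQUARE, 0), make_ring("b", SQUARE, 1)]
        groups = primary_grouping(rings, build_grid(rings))
        assert len(groups) == 1 and len(groups[0].member_rings) == 2

    def test_distant_rings_stay_separate(self):
        rings = [make_ring("a", SQUARE), make_ring("b", SQUARE + 10.0)]
        groups = primary_grouping(rings, build_grid(rings))
        assert sorted(len(g.member_rings) for g in groups) == [1, 1]

    def test_each_ring_contributes_one_o_per_cluster(self, rng):
        rings = [
            make_ring(f"r{i}", SQUARE + rng.normal(0, 0.05, (4, 3)), i)
            for i in range(8)
        ]
        groups = primary_grouping(rings, build_grid(rings))
        assert len(groups) == 1
        for assign in groups[0].assignments:
            assert sorted(assign) == [0, 1, 2, 3]
        for pts in groups[0].o_clusters():
            assert len(pts) == 8

    def test_planted_clusters_match_bruteforce_oracle(self, rng):
        centers = np.array(
            [[0, 0, 0], [6, 0, 0], [0, 7, 0], [-5, -5, 3], [4, -6, -4]], float
        )
        rings = []
        k = 0
        for c in centers:
            for _ in range(20):
                # cyclically rotate member order: order must not matter
                coords = np.roll(SQUARE, k % 4, axis=0)
                rings.append(
                    make_ring(f"r{k:03d}", coords + c + rng.normal(0, 0.1, (4, 3)), k)
                )
                k += 1
        for c in [(20.0, 0, 0), (0, 20.0, 0), (0, 0, 20.0)]:
            rings.append(make_ring(f"r{k:03d}", SQUARE + np.array(c), k))
            k += 1
        groups = primary_grouping(rings, build_grid(rings))
        sizes = sorted(len(g.member_rings) for g in groups)
        assert sizes == [1, 1, 1, 20, 20, 20, 20, 20]
        got = {frozenset(r.ring_id for r in g.member_rings) for g in groups}
        assert got == oracle_partition(rings)


class TestClusterCenters:
    def test_identical_points(self):
        rings = [make_ring(f"r{i}", SQUARE, i) for i in range(5)]
        groups = primary_grouping(rings, build_grid(rings))
        centers = cluster_centers(groups[0])
        assert {tuple(np.round(c, 9)) for c in centers} == {
            tuple(p) for p in SQUARE
        }

    def test_outlier_ignored(self, rng):
        # verified against a reference DBSCAN run: 10 tight points form the
        # largest cluster, the 5 Å outlier is a separate cluster/noise
        from sklearn.cluster import DBSCAN

        pts = np.concatenate(
            [np.zeros((10, 3)) + rng.uniform(-0.05, 0.05, (10, 3)),
             [[5.0, 0.0, 0.0]]]
        )
        from twnscreen.twn_group import _dbscan_center

        center = _dbscan_center(pts, eps=1.0, min_samples=2)
        labels = DBSCAN(eps=1.0, min_samples=2).fit(pts).labels_
        ref = pts[labels == np.bincount(labels[labels >= 0]).argmax()].mean(0)
        assert np.allclose(center, ref)
        assert np.linalg.norm(center) <= 0.05 * np.sqrt(3)

    def test_singleton_group_uses_ring_coords(self):
        rings = [make_ring("a", SQUARE)]
        groups = primary_grouping(rings, build_grid(rings))
        centers = cluster_centers(groups[0])
        assert np.allclose(np.sort(centers, axis=0), np.sort(SQUARE, axis=0))

    def test_all_noise_falls_back_to_mean(self):
        from twnscreen.twn_group import _dbscan_center

        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], float)
        with pytest.warns(UserWarning, match="noise"):
            center = _dbscan_center(pts, eps=0.5, min_samples=2)
        assert np.allclose(center, pts.mean(axis=0))


class TestSecondaryGrouping:
    def _primary(self, coords, ring_id):
        rings = [make_ring(ring_id, coords)]
        return primary_grouping(rings, build_grid(rings))[0]

    def test_identical_centers_merge(self):
        a = self._primary(SQUARE, "a")
        b = self._primary(SQUARE, "b")
        assert len(secondary_grouping([a, b], radius=1.0)) == 1

    def test_offset_centers_do_not_merge(self):
        a = self._primary(SQUARE, "a")
        b = self._primary(SQUARE + 3.0, "b")
        assert len(secondary_grouping([a, b], radius=1.0)) == 2

    def test_chain_merges_transitively(self):
        # A-B and B-C within radius, A-C not: single-linkage closure
        a = self._primary(SQUARE, "a")
        b = self._primary(SQUARE + [0.9, 0, 0], "b")
        c = self._primary(SQUARE + [1.8, 0, 0], "c")
        merged = secondary_grouping([a, b, c], radius=1.0)
        assert len(merged) == 1 and len(merged[0].member_rings) == 3

    def test_radius_boundary_inclusive(self):
        a = self._primary(SQUARE, "a")
        b = self._primary(SQUARE + [1.0, 0.0, 0.0], "b")
        assert len(secondary_grouping([a, b], radius=1.0)) == 1

    def test_larger_radius_never_more_groups(self, rng):
        prims = [
            self._primary(SQUARE + rng.uniform(-3, 3, 3), f"r{i}")
            for i in range(8)
        ]
        counts = [
            len(secondary_grouping(prims, radius=r)) for r in (0.5, 1.0, 2.0, 4.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRingPlane:
    def test_coplanar_points(self):
        n, p0 = ring_plane(SQUARE)
        assert np.allclose(n, [0, 0, 1])
        assert np.allclose(p0[2], 0)

    def test_alternately_lifted_square_symmetry(self):
        pts = SQUARE + np.array([[0, 0, 0.4], [0, 0, -0.4]] * 2)
        n, p0 = ring_plane(pts)
        assert np.allclose(n, [0, 0, 1])
        assert p0[2] == pytest.approx(0.0, abs=1e-12)

    def test_beats_random_planes(self, rng):
        def ssq(pts, n, p0):
            return float(np.sum(np.dot(pts - p0, n) ** 2))

        for _ in range(10):
            pts = rng.uniform(-2, 2, (4, 3))
            try:
                n, p0 = ring_plane(pts)
            except DegenerateGeometryError:
                continue
            best = ssq(pts, n, p0)
            for _ in range(1000):
                rn = rng.normal(size=3)
                rn /= np.linalg.norm(rn)
                assert best <= ssq(pts, rn, pts.mean(axis=0)) + 1e-12

    def test_collinear_raises(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            ring_plane(pts)


@pytest.fixture(scope="module")
def planted_rings():
    frames = make_frames(
        default_demo_sites(), n_frames=30, n_noise_waters=10, rng_seed=11
    )
    return detect_rings(frames), len(frames)


class TestPipelineInvariants:

    def test_partition_covers_all_rings(self, planted_rings):
        rings, n_frames = planted_rings
        groups = group_rings(rings, n_frames=n_frames)
        ids = [r.ring_id for g in groups for r in g.member_rings]
        assert sorted(ids) == sorted(r.ring_id for r in rings)
        assert len(set(ids)) == len(ids)

    def test_permutation_invariance(self, planted_rings, rng):
        rings, n_frames = planted_rings
        a = group_rings(list(rings), n_frames=n_frames)
        shuffled = list(rings)
        rng.shuffle(shuffled)
        b = group_rings(shuffled, n_frames=n_frames)
        assert [sorted(r.ring_id for r in g.member_rings) for g in a] == [
            sorted(r.ring_id for r in g.member_rings) for g in b
        ]
        for ga, gb in zip(a, b):
            assert np.allclose(ga.centroids, gb.centroids, atol=1e-9)

    def test_translation_equivariance(self, planted_rings):
        rings, n_frames = planted_rings
        t = np.array([3.0, -2.0, 1.0])
        moved = [
            TWNRing(r.ring_id, r.frame_id, r.members, r.o_coords + t)
            for r in rings
        ]
        a = group_rings(rings, n_frames=n_frames)
        b = group_rings(moved, n_frames=n_frames)
        for ga, gb in zip(a, b):
            assert np.allclose(gb.centroids, ga.centroids + t, atol=1e-6)

    def test_origin_shift_robustness(self, planted_rings):
        # a 0.25 Å global shift moves grid cell boundaries; the extended-zone
        # linkage must keep the partition identical
        rings, n_frames = planted_rings
        shifted = [
            TWNRing(r.ring_id, r.frame_id, r.members, r.o_coords + 0.25)
            for r in rings
        ]
        a = group_rings(rings, n_frames=n_frames)
        b = group_rings(shifted, n_frames=n_frames)
        assert [sorted(r.ring_id for r in g.member_rings) for g in a] == [
            sorted(r.ring_id for r in g.member_rings) for g in b
        ]

    def test_planted_site_recovery(self, planted_rings):
        from scipy.optimize import linear_sum_assignment

        rings, n_frames = planted_rings
        groups = group_rings(rings, n_frames=n_frames)
        sites = default_demo_sites()
        assert len(groups) == len(sites)
        for g in groups:
            c = np.asarray(g.centroids)
            site = min(
                sites,
                key=lambda s: np.linalg.norm(c.mean(axis=0) - s.center),
            )
            d = np.linalg.norm(
                c[:, None] - site.corner_positions()[None], axis=-1
            )
            row, col = linear_sum_assignment(d)
            assert np.sqrt((d[row, col] ** 2).mean()) < 0.3
            # chord rings can put >1 ring per frame in a group; K4 caps at 3
            assert 0 < g.occupancy <= 3.0
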