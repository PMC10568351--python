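"""Fragment scoring against grouped water-ring sites.

Two superposition-free scores are computed in the shared lab frame:

* **Shape similarity** — each atom is a spherical Gaussian shape density
  ``rho_i(r) = p * exp(-alpha_i * |r - R_i|^2)`` with ``alpha_i`` chosen so
  the Gaussian reproduces the volume of a hard sphere of van der Waals
  radius ``r_i``. The similarity between the grouped site (its four cluster
  centroids as oxygen pseudo-atoms) and the fragment's heavy atoms is the
  Hodgkin index ``2*O_AB / (O_AA + O_BB)`` of the total density overlaps,
  using the closed-form Gaussian product integral.
* **Average plane distance** — the mean orthogonal distance from the
  fragment's heavy-atom centroid to each member ring's best-fit plane.

A fragment pose passes a site when similarity >= s_min (default 0.6) and
average distance <= d_max (default 0.5 Å), both inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_structures import FragmentPose
from .twn_group import GroupedTWN

#: Bondi-style van der Waals radii, Å
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "B": 1.92, "SE": 1.90,
}
DEFAULT_RADIUS = 1.70  # fallback for unlisted elements


@dataclass(frozen=True)
class ShapeParameters:
    """Gaussian shape-density parameters.

    ``p`` is the Gaussian amplitude (2*sqrt(2), the hard-sphere-volume
    convention); ``alpha(r)`` the decay factor reproducing the volume of a
    sphere of radius r. ``normalization`` selects the overlap index:
    ``"hodgkin"`` (2*O_AB/(O_AA+O_BB), default) or ``"minmax"``
    (O_AB/max(O_AA, O_BB)).
    """

    p: float = 2.0 * np.sqrt(2.0)
    radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    normalization: str = "hodgkin"

    def alpha(self, radius: float) -> float:
        return np.pi * (3.0 * self.p / (4.0 * np.pi * radius**3)) ** (2.0 / 3.0)

    def radius_of(self, element: str) -> float:
        return self.radii.get(element.upper(), DEFAULT_RADIUS)


@dataclass(frozen=True)
class ScreenRecord:
    """Scores of one (fragment, group) pair."""

    frag_id: str
    group_id: str
    shape_similarity: float
    avg_distance: float
    passed: bool


def _gaussian_overlap(
    coords_a: np.ndarray, alphas_a: np.ndarray,
    coords_b: np.ndarray, alphas_b: np.ndarray,
    p: float,
) -> float:
    """Sum over atom pairs of the closed-form integral of rho_i * rho_j."""
    asum = alphas_a[:, None] + alphas_b[None, :]
    aprod = alphas_a[:, None] * alphas_b[None, :]
    d2 = np.sum(
        (coords_a[:, None, :] - coords_b[None, :, :]) ** 2, axis=-1
    )
    terms = p * p * (np.pi / asum) ** 1.5 * np.exp(-aprod * d2 / asum)
    return float(terms.sum())


def _alphas(elements, params: ShapeParameters) -> np.ndarray:
    return np.array([params.alpha(params.radius_of(el)) for el in elements])


def shape_similarity(
    twn_points,
    fragment: FragmentPose,
    params: ShapeParameters = ShapeParameters(),
) -> float:
    """Superposition-free Gaussian shape similarity in [0, 1].

    ``twn_points`` are the grouped site's O pseudo-atom positions (the four
    cluster centroids by default, or all member O atoms); the fragment
    contributes its heavy atoms. No rotation or translation is applied to
    either set — both scores live in the lab frame the waters were analysed
    in, so fragment poses must be docked in that same frame.
    """
    twn_points = np.atleast_2d(np.asarray(twn_points, dtype=float))
    heavy = fragment.heavy_atoms()
    if len(heavy) == 0:
        raise ValueError(f"fragment {fragment.frag_id} has no heavy atoms")
    if len(twn_points) == 0:
        raise ValueError("empty pseudo-atom set")
    frag_coords = np.array([xyz for _, xyz in heavy], dtype=float)
    a_o = np.full(len(twn_points), params.alpha(params.radius_of("O")))
    a_f = _alphas([el for el, _ in heavy], params)
    o_ab = _gaussian_overlap(twn_points, a_o, frag_coords, a_f, params.p)
    o_aa = _gaussian_overlap(twn_points, a_o, twn_points, a_o, params.p)
    o_bb = _gaussian_overlap(frag_coords, a_f, frag_coords, a_f, params.p)
    if params.normalization == "hodgkin":
        return 2.0 * o_ab / (o_aa + o_bb)
    if params.normalization == "minmax":
        return o_ab / max(o_aa, o_bb)
    raise ValueError(f"unknown normalization {params.normalization!r}")


def fragment_centroid(fragment: FragmentPose) -> np.ndarray:
    """Unweighted geometric mean of the fragment's heavy-atom coordinates."""
    heavy = fragment.heavy_atoms()
    if not heavy:
        raise ValueError(f"fragment {fragment.frag_id} has no heavy atoms")
    return np.mean([xyz for _, xyz in heavy], axis=0)


def avg_plane_distance(group: GroupedTWN, centroid) -> float:
    """Mean orthogonal distance from a point to the group's member-ring planes."""
    if not group.planes:
        raise ValueError(f"group {group.group_id} has no planes")
    c = np.asarray(centroid, dtype=float)
    return float(
        np.mean([abs(np.dot(n, c - p0)) for n, p0 in group.planes])
    )


def score_pair(
    fragment: FragmentPose,
    group: GroupedTWN,
    params: ShapeParameters = ShapeParameters(),
    use_all_o: bool = False,
) -> tuple[float, float]:
    """(shape similarity, average plane distance) of one pair.

    ``use_all_o`` switches the site representation from the four cluster
    centroids to every member ring's O atoms.
    """
    if use_all_o and group.member_rings:
        pts = np.concatenate(
            [np.asarray(r.o_coords, dtype=float) for r in group.member_rings]
        )
    else:
        pts = np.asarray(group.centroids, dtype=float)
    s = shape_similarity(pts, fragment, params)
    d = avg_plane_distance(group, fragment_centroid(fragment))
    return s, d


def screen(
    fragments,
    groups,
    s_min: float = 0.6,
    d_max: float = 0.5,
    params: ShapeParameters = ShapeParameters(),
    use_all_o: bool = False,
) -> list[ScreenRecord]:
    """Score every (fragment, group) pair; thresholds are inclusive.

    Poses are expected in the same lab frame as the water analysis; a
    fragment whose centroid falls far outside the bounding box of all group
    centroids triggers a coordinate-frame sanity warning.
    """
    import warnings

    groups = list(groups)
    fragments = list(fragments)
    if groups:
        all_c = np.concatenate([np.asarray(g.centroids) for g in groups])
        lo, hi = all_c.min(axis=0) - 15.0, all_c.max(axis=0) + 15.0
        for frag in fragments:
            c = fragment_centroid(frag)
            if np.any(c < lo) or np.any(c > hi):
                warnings.warn(
                    f"fragment {frag.frag_id} centroid {np.round(c, 1)} is far "
                    "outside the grouped-network region; check that poses are "
                    "docked in the same coordinate frame as the water analysis"
                )
    records: list[ScreenRecord] = []
    for frag in fragments:
        for group in groups:
            s, d = score_pair(frag, group, params, use_all_o)
            records.append(
                ScreenRecord(
                    frag_id=frag.frag_id,
                    group_id=group.group_id,
                    shape_similarity=s,
                    avg_distance=d,
                    passed=(s >= s_min) and (d <= d_max),
                )
            )
    return records


def screened_fragments(
    records, s_min: float = 0.6, d_max: float = 0.5
) -> list[str]:
    """Fragments that pass against at least one group, in first-seen order."""
    out: list[str] = []
    seen = set()
    for r in records:
        if r.frag_id in seen:
            continue
        if r.shape_similarity >= s_min and r.avg_distance <= d_max:
            seen.add(r.frag_id)
            out.append(r.frag_id)
    return out


def threshold_sweep(
    records,
    s_grid=(0.5, 0.6, 0.7),
    d_grid=(0.3, 0.5, 1.0),
) -> pd.DataFrame:
    """Screened-fragment counts over a grid of (s_min, d_max) thresholds.

    Returns one row per threshold pair with the count and percentage of
    fragments passing at least one group — the summary used to pick the
    final screening criteria.
    """
    frag_ids = sorted({r.frag_id for r in records})
    n = len(frag_ids)
    rows = []
    for s_min in s_grid:
        for d_max in d_grid:
            passed = screened_fragments(records, s_min, d_max)
            rows.append(
                {
                    "s_min": s_min,
                    "d_max": d_max,
                    "n_screened": len(passed),
                    "pct_screened": 100.0 * len(passed) / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)
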