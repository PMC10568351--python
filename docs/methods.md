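# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, so that results can be interpreted — and
questioned — without reading the source.

## Pair potential and hydrogen-bond criterion

Waters are rigid three-site molecules. The pair energy is the full 3×3
Coulomb sum over partial charges (O −0.834 e, H +0.417 e) plus a single
Lennard-Jones term on the O–O distance (A = 582 000 kcal·Å¹²·mol⁻¹,
C = 595 kcal·Å⁶·mol⁻¹). The Coulomb conversion constant e² is fixed at
332.0636 kcal·Å·mol⁻¹·e⁻², the CHARMM convention consistent with frames
produced by a CHARMM/TIP3P simulation. Explicit hydrogen coordinates from
the input are used as-is; no idealisation is applied, since the intended
inputs come from a rigid-water simulation.

A pair is hydrogen-bonded when v ≤ −2.25 kcal·mol⁻¹. The comparison is
**inclusive**; the criterion's source states it as a threshold without
fixing strictness, and ≤ is the convention adopted (and tested) here. The
same inclusiveness applies to the site radius, the 1 Å secondary-grouping
radius, and both screening thresholds.

**Neighbor cutoff.** Pairs beyond a cutoff O–O distance are skipped without
energy evaluation. The cutoff must be conservative: orientation-optimised
rigid TIP3P pairs still reach −2.25 kcal·mol⁻¹ at O–O separations up to
≈4.1 Å (numerically, the orientation-minimised pair energy is −3.45 at
3.6 Å, −2.46 at 4.0 Å and −2.11 at 4.2 Å). The default is therefore
**4.25 Å**, which provably cannot drop a hydrogen-bonded pair; the
equivalence with exhaustive all-pairs evaluation is tested. A tighter
cutoff (e.g. 3.6 Å) would be faster but silently loses rare well-oriented
long bonds.

## Ring definition

Rings are simple 4-cycles of the per-frame hydrogen-bond graph. Chords are
permitted — a 4-clique yields its three distinct cycles — because the
method imposes no chordless condition and keeps non-planar rings. Each
4-water set is reported once in canonical cyclic order (smallest member id
first, smaller neighbor second), which makes ring identity deterministic
and input-order independent. Site membership is judged by the ring's
O-centroid against an inclusive sphere; centroid (rather than any-atom or
all-atom) is the least ambiguous single criterion.

## Grouping

* **Grid.** 0.5 Å half-open cubic cells; origin = componentwise minimum of
  all O coordinates snapped down to a multiple of the spacing. The origin is
  arbitrary; robustness to it comes from the extended-zone (±1 cell)
  linkage and is tested by shifting all coordinates 0.25 Å and asserting an
  identical partition.
* **Primary linkage.** Two rings link when a one-to-one correspondence of
  their four O atoms exists with every matched pair inside each other's
  3×3×3 cell neighborhood. The correspondence is chosen by minimum-cost
  assignment on the 4×4 distance matrix (infeasible pairings masked), and
  propagated over a spanning tree so each member ring contributes exactly
  one O atom per cluster; ring cyclic order is deliberately not trusted
  across frames. Groups are connected components of this relation.
* **Cluster centers.** DBSCAN per O cluster, default eps = 1.0 Å,
  min_samples = 1 (no published values exist for this step; with
  min_samples = 1 every point joins a cluster and the center is the mean of
  the largest one, which degrades gracefully to the plain mean for tight
  unimodal clusters). An all-noise outcome falls back to the plain mean
  with a warning.
* **Secondary linkage.** Single-linkage transitive closure over the
  pairwise criterion "four centers match one-to-one within ≤ 1 Å"
  (minimum-cost assignment, max matched distance). Merged groups pool their
  O clusters following the center correspondence and **re-derive** the four
  centroids from pooled points (re-running DBSCAN), rather than averaging
  the primary centers — a possible divergence from the original tool, noted
  as such. Final centroids are ordered lexicographically so outputs are
  byte-reproducible regardless of input order.
* **Planes.** One total-least-squares plane per member ring through its
  four O atoms (SVD of the centered coordinates; normal sign fixed to
  positive z, tie-broken by y then x); collinear quadruples raise a
  degenerate-geometry error. The distance score averages over these
  per-ring planes, so groups containing many rings are represented by their
  full spread of plane orientations.

## Fragment scoring

Atom *i* contributes a spherical Gaussian shape density
ρ_i(r) = p·exp(−α_i‖r−R_i‖²) with p = 2√2 and
α_i = π(3p/(4πr_i³))^(2/3), the choice that makes the Gaussian reproduce
the volume of a hard sphere of van der Waals radius r_i (Bondi radii;
O 1.52, C 1.70, N 1.55, S 1.80 Å, …; unlisted elements default to 1.70 Å).
Overlaps use the closed-form Gaussian product integral; no quadrature at
run time (a quadrature oracle exists in the tests). The similarity is the
Hodgkin index 2·O_AB/(O_AA+O_BB); a min/max normalisation
(O_AB/max(O_AA,O_BB)) is available behind a flag. The grouped network is
represented by its four cluster centroids as oxygen pseudo-atoms by
default; a flag switches to all member-ring O atoms (the original tool's
representation is not documented; centroids are the more compact summary
and match the plane construction).

Both scores are computed strictly in the shared lab frame — no rotation or
translation of either set — so fragment poses **must** be docked in the
same coordinate frame as the water analysis. Fragment centroid and shape
use heavy atoms only; hydrogens are read and retained but flagged out.

Screening: pass ⇔ S ≥ s_min (0.6) and D ≤ d_max (0.5 Å), inclusive; a
fragment counts as screened when it passes against at least one group. The
threshold-sweep table reports screened counts over
{0.5, 0.6, 0.7} × {0.3, 0.5, 1.0}.

## Synthetic study conditions

The generator plants square rings (O–O edge 2.8 Å, i.e. half-diagonal
1.98 Å — firmly inside the hydrogen-bond well) at fixed sites. Each water
donates one hydrogen toward the next ring oxygen; the free hydrogen lies in
the ring plane tilted outward, the orientation that puts every consecutive
pair near −6.1 kcal·mol⁻¹ while the diagonal pairs stay above the
threshold (≈ −1.9), so a clean ring yields exactly one 4-cycle. Positional
jitter (Gaussian, default σ = 0.1 Å) is applied to the O corners before
hydrogens are rebuilt toward the jittered neighbors; at σ = 0 validity of
the fixture is recomputed in the tests, not assumed. Noise waters are
uniform in a 30 Å box with random orientations, rejection-sampled at least
4 Å from any planted oxygen so noise rarely forms competing rings. The
default study uses 5 sites with pairwise separations ≥ 4 Å inside a 20 Å
sphere, 200 frames and 30 noise waters per frame — a deliberately
desk-scale stand-in for the thousand-snapshot trajectories the tool
consumes in production.

What the generator does **not** emulate: water dynamics, realistic
hydrogen-bond geometry distributions, partially formed or 3-/5-membered
networks, protein atoms, and correlated frame-to-frame motion. Passing the
planted-recovery tests therefore shows the detection/grouping/screening
machinery is correct, not that any particular protein has recoverable
hot spots.

## Numerical and interface choices

* Frames are treated as a single static lab frame; no alignment is
  performed (intended inputs come from protein-restrained simulations).
  Periodic box vectors are read but minimum-image searching is off by
  default.
* Waters are recognised by residue name (HOH/SOL/WAT/TIP3, configurable);
  incomplete waters (missing H) are skipped and counted in a logged
  warning, never silently.
* Energies below an O–O separation of 0.1 Å raise a degenerate-geometry
  error rather than returning astronomically large values.
* All CLI randomness flows from one seed; outputs carry no timestamps, so
  identical inputs + seed give byte-identical outputs (tested).
* Exit codes: 0 success, 2 input error, 3 empty result.

## Known limitations

* Only 4-membered rings are analysed; no thermodynamic quantities
  (occupancy free energies, enthalpy/entropy) are computed — by design.
* Screening quality is bounded by the docking poses supplied: poses in a
  different coordinate frame score near zero (a bounding-box sanity warning
  is the only guard).
* DBSCAN parameters for the center-finding step and the TWN shape
  representation (centroids vs all O atoms) are documented defaults, not
  values with a published source; both are exposed as options.
* Primary grouping scales with the number of near-coincident ring pairs;
  at the default study sizes (≈10³ rings) it runs in under a second, and
  the acceptance run completes in a few seconds on one core.
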