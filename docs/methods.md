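# Methods

## The estimation problem

Body segment parameters (BSP) — per-segment mass `m_i`, centre of mass
`c_i`, and inertia tensor `I_i` — are required by inverse dynamics but are
not directly measurable in vivo. This package implements a geometric
estimator that takes three inputs: a scaled surface point cloud of a
standing subject (the output of a photogrammetric reconstruction; producing
that cloud is outside the package's scope), a named landmark set, and the
subject's measured mass and height. Everything downstream — segmentation,
hulling, integration, mass closure — is computed, not looked up.

## Geometry kernel

**Convex hulls.** Each segment cloud is closed with its minimum convex hull
(qhull, via `scipy.spatial.ConvexHull`), re-wound so all face normals point
outward. The hull is the deliberate choice over concave reconstructions: it
is parameter-free, fast, and robust to sparse or hole-ridden clouds, at the
cost of always overestimating the volume of concave shapes. Degenerate
input (fewer than four points, coplanar or collinear clouds) raises an
error rather than returning a zero-volume shell — a silent zero would poison
the pro-rata mass scaling downstream.

**Exact polyhedral integration.** For a watertight, outward-oriented
triangle mesh, volume, first moments and second moments are accumulated per
signed tetrahedron (face + apex). With tetrahedron vertices `0, a, b, c`
and `d = a · (b × c)`:

    ∫ dV        = d / 6
    ∫ x dV      = d (a + b + c) / 24
    ∫ xᵢxⱼ dV   = d [ (a+b+c)(a+b+c)ᵀ + aaᵀ + bbᵀ + ccᵀ ]ᵢⱼ / 120

(the last following from barycentric moment integrals
`∫ λₖλₗ dV = V (1+δₖₗ)/20`). The inertia tensor about the origin is
`ρ (tr C · Id − C)` with `C` the second-moment matrix, then moved to the CoM
by the parallel-axis theorem. The mesh is pre-translated to its vertex
centroid before integration and the results translated back: the signed
sums are origin-invariant analytically, and the shift keeps them
well-conditioned numerically (verified to 1e-9 relative under 100 m
offsets). Products of inertia are stored signed, as the off-diagonals of
`I = ∫ρ(‖r‖² Id − r rᵀ)dV` (i.e. `Ixy = −∫ρxy dV`); report writers also
emit their unsigned magnitudes.

**Validation.** Watertightness and winding coherence are exact
combinatorial checks on the edge–face incidence structure (every undirected
edge on exactly two faces; the two incident faces traverse it in opposite
directions); no geometric epsilon is involved, since hulls are
combinatorially clean by construction. `mass_properties` refuses meshes
that fail either check or have non-positive signed volume.

**Composition.** Subdivided parts recombine by mass-weighted CoM and the
full parallel-axis shift `I += m (‖d‖² Id − ddᵀ)` including off-diagonal
terms; plane-splitting a convex body and recombining reproduces the whole
to 1e-6 relative.

## Segmentation

Units are SI throughout (m, kg, kg·m²); display scaling is left to report
consumers. The world frame is right-handed with +z vertical in the
anatomical standing pose, x anterior, y lateral. A raw scan is brought into
this frame by one similarity transform fixed by a landmark pair of known
metric distance (e.g. head–floor at the measured stature) and an up-hint
pair rotated onto +z.

Segments are defined entirely by configuration (YAML/JSON), not hard-coded
anatomy: each has a density, proximal/distal landmarks, a longitudinal axis
convention (z, or x for the foot), and a conjunction of half-spaces whose
cutting planes are given by one landmark on the plane and a landmark pair
for the normal. The shipped default is the 14-segment set reported for
whole-body scans — head, trunk, and left/right upper arm, forearm, hand,
thigh, shank, foot — with horizontal joint planes plus lateral armpit
planes separating the hanging arms from the trunk.

Tie-break: a point exactly on a cutting plane belongs to the more
proximal/axial segment. This is implemented by listing specs
proximal-first and assigning each point to the first spec whose half-spaces
it satisfies (boundary inclusive), which also makes the partition total and
deterministic. Points satisfying no spec (possible only for configs whose
half-spaces do not cover space) fall back to the least-violated segment so
no point is ever dropped.

Each segment then gets a rigid anatomical frame: origin at the proximal
landmark, longitudinal axis toward the distal landmark, remaining axes
completed right-handedly against the world anterior/vertical directions.
CoM output is `100 · c_axis / L` from the proximal landmark, with the
transverse off-axis shift normalised the same way; mirrored segments
produce lateral shifts of equal size and opposite sign.

## Mass closure and corrections

With hull volumes `V_i` and densities `ρ_i` (trunk 940 kg/m³ — deliberately
below soft tissue to absorb lung air enclosed by a surface scan — and
1000 kg/m³ elsewhere), the raw masses `ρ_iV_i` never sum exactly to the
measured subject mass, both because of density error and hull
overestimation. The pro-rata factor

    s = m_subject / Σ m_hull,i

is applied to every mass and to the full inertia tensor; it is equivalent
to rescaling all densities by `s`, which is why the products of inertia
scale too. Volumes are reported unscaled (and flagged as such), since they
are geometric measurements, not density-dependent estimates. A useful
consequence, tested by construction: if every hull overestimates volume by
the same factor, the final masses are exact.

The foot-in-shoe correction (default 0.51, the sock/shoe hull-volume ratio
measured on one participant in the source workflow; set 1.0 for barefoot
scans) multiplies the feet's mass, volume and inertia *before* `s` is
computed, so the closure reflects corrected hull masses. The ordering is a
package decision — correcting first keeps "scaled masses sum to body mass"
true of the reported rows.

Subdivision defaults to one mid-length cut on the strongly curved distal
segments (foot, shank, forearm, hand) and is fully overridable; cut planes
are perpendicular to the longitudinal axis at fractions of the cloud's
longitudinal extent, boundary points going to the proximal part. On convex
segments subdivision is volume-neutral (to hull-tessellation noise); on
concave ones it monotonically reduces the hull's overestimation —
quantified by `overestimation_report` as `100 (V_hull − V_ref)/V_ref`
against a reference volume.

## Synthetic bodies: what they emulate, and what they do not

The generator poses primitive solids (sphere, ellipsoid, cylinder,
truncated cone) as body segments with exact closed-form volume/CoM/inertia;
truncated-cone integrals are evaluated as exact polynomials in the axial
coordinate, and the equal-radius case reproduces the cylinder closed form.
The default humanoid is 14 segments — matching the default segmentation,
so generator and pipeline agree on the anatomy — in the standing pose with
arms held laterally clear of the trunk so that landmark-defined planes
separate every segment exactly. All proportions scale with stature;
densities start at the trunk/uniform defaults and are rescaled by one
common factor so true masses sum exactly to the requested total (the same
pro-rata logic the pipeline applies).

The **bent cylinder** supplies controlled concavity: a disc of radius `r`
swept along a circular arc whose centreline length equals the straight
length `L`, so its volume is exactly `πr²L` by Pappus's theorem. Its
inertia has no convenient closed form and comes from a voxel oracle
(inside-test on a regular grid, 1 mm default resolution, per-voxel
self-inertia included), which is flagged approximate. At a 50° bend the
whole-segment hull overestimates the true volume by ≈ 29 % and one
mid-length cut reduces this to ≈ 8 % — the same direction and rough
magnitude as the shank/forearm behaviour that motivates subdivision.

Surface sampling is area-weighted per face component (lateral walls by
rejection on the local radius), deterministic given a seed, with optional
Gaussian noise. Holes are modelled as one contiguous **occlusion band** — a
slab of random orientation through the middle of each primitive's cloud,
removing exactly `round(n·f)` points — because that is the dropout shape a
ring of cameras at one height actually produces (strips at poorly covered
heights and occlusion shadows), and it is the regime in which convex
hulling's robustness claim holds: a 20 % band changes convex hull volumes
by ≈ 1 %. A hole that removed an extremal cap would cost the hull real
volume; such pathologies are not what photogrammetric gaps look like and
are not modelled.

What passing synthetic tests does **not** show: real scans have
non-primitive cross-sections, soft-tissue and clothing deformation,
landmark placement error, and pose deviations; parameter-recovery numbers
here bound the *geometric* pipeline error only, not anthropometric model
error or density misassignment.

## Numerical choices and problem sizes

* Hull/integration tolerances: validity checks are combinatorial;
  orientation uses exact sign tests on signed volume. Rotation matrices
  are accepted orthonormal to 1e-6.
* Default fixture sizes: 20 000 surface points per segment for recovery
  studies (hull volume deficit of a sampled convex body scales as
  `n^(−2/3)` and is ≈ 0.1–0.5 % there), 10⁶ Monte-Carlo samples for oracle
  comparisons, 1 mm voxels for bent-segment truth. These sizes put
  sampling error well below the tolerances being asserted while keeping
  any single computation in the seconds range.
* Monte-Carlo and voxel oracles live in the test/acceptance layer, not the
  implementation; the implementation path is exact integration.
* Report serialisation: CSV at 6 significant digits for stable diffs; JSON
  at full precision; coordinate files written with `%.17g` so round-trips
  are bit-exact. No timestamps are written, so seeded runs are
  byte-reproducible.

## Known limitations

* Convex hulls overestimate concave segments; subdivision mitigates but
  does not eliminate this (hands with spread fingers remain the worst
  case). Concave hulling (alpha shapes, ball pivoting) is deliberately out
  of scope.
* The default segmentation approximates standard reference-point
  definitions; it is a documented configuration, not a validated claim of
  anatomical equivalence.
* Two densities (trunk/other) only; population- or segment-specific
  density libraries are not included.
* Whether reported volumes should carry the `s` scaling is convention-
  dependent; this package reports them unscaled and says so in the report
  header fields.
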