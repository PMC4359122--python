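# hullbsp

Subject-specific **body segment inertial parameters (BSP)** — per-segment
mass, centre of mass and the full 3×3 inertia tensor — estimated from a 3D
surface scan of a standing person, as produced by photogrammetric (structure
from motion) body scanners.

Inverse-dynamics analyses of human movement need BSP values, but they cannot
be measured directly. Regression tables (Dempster, Zatsiorsky/de Leva) only
fit populations similar to their source cadaver/participant samples. This
package implements a geometric alternative: the scanned point cloud is cut
into anatomical segments at landmark-defined planes, each segment is closed
with its **minimum convex hull**, and exact polyhedral integration over the
hull gives volume, CoM and inertia under segment-density assumptions.

The core model, in the field's standard notation:

* Each segment hull is integrated exactly by signed-tetrahedron
  decomposition: `V = ∫dV`, `c = ∫r dV / V`, and
  `I = ∫ρ(‖r‖² Id − r rᵀ) dV` about the CoM, so moments *and* products of
  inertia are produced (products are otherwise simply assumed zero in
  regression tables).
* Segment mass is `m_i = ρ_i V_i` with a trunk density of **940 kg/m³**
  (lungs included in a surface scan) and **1000 kg/m³** elsewhere.
* A convex hull always overestimates the volume of a concave segment, so the
  mass budget is closed pro-rata with

  `s = m_subject / Σᵢ m_hull,i`

  applied to every segment mass and to the full inertia tensor (the factor
  effectively rescales the densities). Curved segments (shank, forearm,
  hand, foot) can additionally be **subdivided** perpendicular to their long
  axis and hulled per part, which shrinks the overestimation; part hulls are
  recombined with the parallel-axis theorem.
* A foot-in-shoe correction factor (default **0.51**) accounts for scans
  taken wearing shoes; it is applied to the feet's mass, volume and inertia
  before `s` is computed.
* CoM positions are reported as % of segment length from the proximal
  landmark along the anatomical longitudinal axis (z, or x for the foot),
  plus the transverse (off-axis) shift.

A first-class synthetic-data generator (`hullbsp.synthetic_body`) builds
parametric humanoids out of primitive solids with closed-form inertial
ground truth, surface-samples them with controllable noise and occlusion
holes, and provides a concave *bent cylinder* (volume-preserving arc sweep)
for studying hull overestimation.

## Worked example

```python
import numpy as np
from hullbsp import (PointCloud, SubjectRecord, compute_body_bsp,
                     convex_hull, generate_default_humanoid, mass_properties)

# exact polyhedral integration: the unit cube at 1000 kg/m^3
corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
props = mass_properties(convex_hull(PointCloud(corners)), density=1000.0)
print(f"volume = {props.volume:.6f} m^3, mass = {props.mass:.1f} kg")
print(f"Ixx    = {props.inertia_com[0,0]:.4f} kg m^2")

# end-to-end on a synthetic scan: 14 segments, 5000 surface points each
body = generate_default_humanoid(height=1.80, total_mass=90.3)
cloud, _ = body.sample(n_points_per_segment=5000, seed=1)
bsp = compute_body_bsp(cloud, body.segmentation(),
                       SubjectRecord("demo", mass=90.3, height=1.80),
                       foot_factor=1.0)   # synthetic subject is barefoot
print(f"s = {bsp.scaling_factor:.4f}")
for row in bsp.segments[:4]:
    print(f"{row.name:10s} {row.mass:7.3f} kg  {row.mass_percent:5.2f} %  "
          f"CoM {row.com_longitudinal_percent:5.1f} %")
print(f"total mass = {sum(r.mass for r in bsp.segments):.10f} kg")
```

prints

```
volume = 1.000000 m^3, mass = 1000.0 kg
Ixx    = 166.6667 kg m^2
s = 0.7967
head         3.230 kg   3.58 %  CoM  54.2 %
trunk       38.437 kg  42.57 %  CoM  50.0 %
left_upper_arm   4.314 kg   4.78 %  CoM  46.6 %
left_forearm   2.159 kg   2.39 %  CoM  45.7 %
total mass = 90.3000000000 kg
```

The cube values are the closed forms (`m L²/6 = 166.667 kg·m²`). In the
pipeline run, `s ≈ 0.80` closes the gap between the hull-derived mass at the
assumed densities and the subject's measured 90.3 kg; the reported segment
masses sum to the subject mass exactly, and each is within 2 % of the
generator's analytic truth.

The same pipeline is available from the shell:

```sh
hullbsp synth --height 1.80 --mass 90.3 --seed 1 -o body/
hullbsp bsp body/ --subject-mass 90.3 -o report/   # writes bsp.json + bsp.csv
hullbsp hull body/cloud.ply -o hull.ply
hullbsp validate hull.ply
```

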