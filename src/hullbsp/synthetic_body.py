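"""Parametric humanoids and test solids with closed-form inertial ground truth.

Stands in for scanner output: primitive solids (spheres, cylinders, truncated
cones, ellipsoids) are posed as body segments and surface-sampled into point
clouds with controllable Gaussian noise and contiguous missing-patch "holes".
A bent cylinder — a circular-arc sweep of a disc whose centreline length
equals the straight length, so its volume is exactly ``π r² L`` by Pappus —
provides a controllable concave analogue of the shank/forearm curvature that
drives convex-hull volume overestimation.

Local primitive conventions (before the pose transform):

* ``sphere``      – radius ``r``, centred at the origin.
* ``ellipsoid``   – semi-axes ``a, b, c`` along x, y, z, centred at the origin.
* ``cylinder``    – radius ``r``, axis +z, base disc at z = 0, top at z = L.
* ``truncated_cone`` – radii ``r_base`` (z = 0) → ``r_top`` (z = L), axis +z.
* ``bent_cylinder``  – disc of radius ``r`` swept along a circular arc of
  centreline length ``L`` and bend angle ``angle`` (radians, ≤ π/2); the arc
  starts at the origin with tangent +z and bends towards +x; the arc centre
  sits at (L/angle, 0, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .mesh_core import (
    GeometryError,
    InertialProperties,
    PointCloud,
    RigidTransform,
    combine_properties,
    transform_properties,
)
from .segmentation import (
    TRUNK_DENSITY,
    UNIFORM_DENSITY,
    BodySegmentation,
    default_segmentation,
)

__all__ = [
    "PrimitiveSpec",
    "SyntheticBody",
    "analytic_properties",
    "voxel_properties",
    "sample_surface",
    "generate_default_humanoid",
]

_KINDS = ("sphere", "cylinder", "truncated_cone", "ellipsoid", "bent_cylinder")

#: Voxel edge length (m) of the numeric oracle used for bent-cylinder truth.
DEFAULT_VOXEL_RESOLUTION = 1e-3


@dataclass(frozen=True)
class PrimitiveSpec:
    """One posed primitive solid with uniform density and endpoint landmarks."""

    kind: str
    dimensions: Mapping[str, float]
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    density: float = UNIFORM_DENSITY
    landmarks: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise GeometryError(f"unknown primitive kind {self.kind!r}; expected one of {_KINDS}")
        dims = {k: float(v) for k, v in self.dimensions.items()}
        for k, v in dims.items():
            if v <= 0:
                raise GeometryError(f"{self.kind} dimension {k!r} must be positive, got {v}")
        if self.kind == "bent_cylinder":
            ang = dims.get("angle", 0.0)
            if not (0.0 < ang <= math.pi / 2):
                raise GeometryError("bend angle must be in (0, pi/2] radians")
            radius_arc = dims["length"] / ang
            if dims["radius"] >= radius_arc:
                raise GeometryError("bend too tight: tube radius exceeds arc radius")
        object.__setattr__(self, "dimensions", dims)
        object.__setattr__(
            self,
            "landmarks",
            {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.landmarks.items()},
        )

    def posed_landmarks(self) -> dict[str, np.ndarray]:
        return {k: self.pose.apply(v) for k, v in self.landmarks.items()}


# ---------------------------------------------------------------------------
# Closed-form and voxel-oracle inertial properties
# ---------------------------------------------------------------------------

def _poly_int(coeffs: np.ndarray, upper: float) -> float:
    """∫₀^upper of the polynomial with ascending ``coeffs``."""
    p = np.polynomial.Polynomial(coeffs)
    return float(p.integ()(upper))


def _frustum_local(r0: float, r1: float, L: float, rho: float) -> InertialProperties:
    """Solid of revolution r(z) = r0 + (r1-r0) z/L about the z axis, exact."""
    rz = np.array([r0, (r1 - r0) / L])
    r2 = np.polynomial.polynomial.polymul(rz, rz)
    r4 = np.polynomial.polynomial.polymul(r2, r2)
    V = math.pi * _poly_int(r2, L)
    zbar = math.pi * _poly_int(np.polynomial.polynomial.polymul(r2, [0.0, 1.0]), L) / V
    m = rho * V
    Iz = rho * math.pi / 2.0 * _poly_int(r4, L)
    # about x through the base centre: ∫(y² + z²) dV = π∫(r⁴/4 + r² z²) dz
    Ix_base = rho * math.pi * (
        _poly_int(r4, L) / 4.0
        + _poly_int(np.polynomial.polynomial.polymul(r2, [0.0, 0.0, 1.0]), L)
    )
    Ix = Ix_base - m * zbar**2
    return InertialProperties(
        volume=V, mass=m, com=np.array([0.0, 0.0, zbar]),
        inertia_com=np.diag([Ix, Ix, Iz]), frame="world",
    )


def _bent_inside(dims: Mapping[str, float]) -> tuple[Callable[[np.ndarray], np.ndarray], np.ndarray]:
    """Vectorised inside-test and axis-aligned bounds for a local bent cylinder."""
    r = dims["radius"]
    L = dims["length"]
    theta = dims["angle"]
    Rb = L / theta

    def inside(p: np.ndarray) -> np.ndarray:
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        t = np.arctan2(z, Rb - x)
        d = np.hypot(Rb - x, z)
        u = Rb - d  # in-plane offset from the centreline, towards the arc centre
        return (t >= 0) & (t <= theta) & (u * u + y * y <= r * r)

    hi_z = (Rb + r) * math.sin(theta) + r
    bounds = np.array([
        [-r, Rb - (Rb - r) * math.cos(theta) + r],
        [-r, r],
        [-1e-9, hi_z],
    ])
    return inside, bounds


def voxel_properties(
    inside: Callable[[np.ndarray], np.ndarray],
    bounds: np.ndarray,
    density: float,
    resolution: float = DEFAULT_VOXEL_RESOLUTION,
    frame: str = "world",
) -> InertialProperties:
    """Numeric mass-property oracle: voxelise an inside-test on a regular grid.

    Used as the documented approximate "truth" for shapes without closed
    forms (the bent cylinder).  Accuracy is O(resolution); the per-voxel cube
    self-inertia term ``m h²/6`` is included.
    """
    h = resolution
    bounds = np.asarray(bounds, dtype=float)
    axes = [np.arange(lo + h / 2, hi, h) for lo, hi in bounds]
    nx, ny = len(axes[0]), len(axes[1])
    xy = np.stack(np.meshgrid(axes[0], axes[1], indexing="ij"), axis=-1).reshape(-1, 2)
    count = 0
    first = np.zeros(3)
    second = np.zeros((3, 3))
    for z in axes[2]:  # slab at a time to bound memory
        p = np.empty((len(xy), 3))
        p[:, :2] = xy
        p[:, 2] = z
        m = inside(p)
        if not m.any():
            continue
        q = p[m]
        count += len(q)
        first += q.sum(axis=0)
        second += q.T @ q
    if count == 0:
        raise GeometryError("voxel oracle found no interior voxels; check bounds/resolution")
    vol = count * h**3
    mass = density * vol
    com = first / count
    I_origin = density * h**3 * (np.trace(second) * np.eye(3) - second)
    I_origin += mass * h**2 / 6.0 * np.eye(3)
    I_com = I_origin - mass * (np.dot(com, com) * np.eye(3) - np.outer(com, com))
    return InertialProperties(volume=vol, mass=mass, com=com,
                              inertia_com=0.5 * (I_com + I_com.T), frame=frame)


def analytic_properties(
    p: PrimitiveSpec,
    voxel_resolution: float = 2e-3,
) -> InertialProperties:
    """Ground-truth volume/CoM/inertia of a primitive, in the posed frame.

    Sphere, cylinder, truncated cone and ellipsoid use exact closed forms.
    The bent cylinder has no simple closed form for its inertia and uses the
    voxel oracle at ``voxel_resolution`` (its volume is exactly ``π r² L`` by
    Pappus; the voxel estimate converges to it).  Bent-cylinder results are
    therefore approximate at the oracle resolution.
    """
    d = p.dimensions
    rho = p.density
    if p.kind == "sphere":
        r = d["radius"]
        V = 4.0 / 3.0 * math.pi * r**3
        m = rho * V
        I = 2.0 / 5.0 * m * r**2
        local = InertialProperties(V, m, np.zeros(3), np.diag([I, I, I]), frame="world")
    elif p.kind == "ellipsoid":
        a, b, c = d["a"], d["b"], d["c"]
        V = 4.0 / 3.0 * math.pi * a * b * c
        m = rho * V
        local = InertialProperties(
            V, m, np.zeros(3),
            np.diag([m / 5 * (b**2 + c**2), m / 5 * (a**2 + c**2), m / 5 * (a**2 + b**2)]),
            frame="world",
        )
    elif p.kind == "cylinder":
        r, L = d["radius"], d["length"]
        local = _frustum_local(r, r, L, rho)
    elif p.kind == "truncated_cone":
        local = _frustum_local(d["r_base"], d["r_top"], d["length"], rho)
    elif p.kind == "bent_cylinder":
        inside, bounds = _bent_inside(d)
        local = voxel_properties(inside, bounds, rho, resolution=voxel_resolution)
    else:  # pragma: no cover - guarded in __post_init__
        raise GeometryError(f"unknown primitive kind {p.kind!r}")
    return transform_properties(local, p.pose)


# ---------------------------------------------------------------------------
# Surface sampling
# ---------------------------------------------------------------------------

def _sample_disc(rng, n: int, r: float) -> np.ndarray:
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    rad = r * np.sqrt(rng.uniform(0.0, 1.0, n))
    return np.column_stack([rad * np.cos(phi), rad * np.sin(phi)])


def _sample_primitive_surface(p: PrimitiveSpec, n: int, rng) -> np.ndarray:
    d = p.dimensions
    if p.kind == "sphere":
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        return d["radius"] * dirs
    if p.kind == "ellipsoid":
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        return dirs * np.array([d["a"], d["b"], d["c"]])
    if p.kind in ("cylinder", "truncated_cone"):
        if p.kind == "cylinder":
            r0 = r1 = d["radius"]
        else:
            r0, r1 = d["r_base"], d["r_top"]
        L = d["length"]
        slant = math.hypot(L, r1 - r0)
        areas = np.array([math.pi * (r0 + r1) * slant, math.pi * r0**2, math.pi * r1**2])
        comp = rng.choice(3, size=n, p=areas / areas.sum())
        out = np.empty((n, 3))
        lat = comp == 0
        n_lat = int(lat.sum())
        if n_lat:
            # z density on the lateral wall is proportional to r(z): rejection-sample
            rmax = max(r0, r1)
            zs = np.empty(0)
            while len(zs) < n_lat:
                cand = rng.uniform(0.0, L, 2 * n_lat)
                acc = rng.uniform(0.0, 1.0, 2 * n_lat) <= (r0 + (r1 - r0) * cand / L) / rmax
                zs = np.concatenate([zs, cand[acc]])
            zs = zs[:n_lat]
            rz = r0 + (r1 - r0) * zs / L
            phi = rng.uniform(0.0, 2.0 * math.pi, n_lat)
            out[lat] = np.column_stack([rz * np.cos(phi), rz * np.sin(phi), zs])
        for which, r_cap, z_cap in ((1, r0, 0.0), (2, r1, L)):
            sel = comp == which
            k = int(sel.sum())
            if k:
                uv = _sample_disc(rng, k, r_cap)
                out[sel] = np.column_stack([uv, np.full(k, z_cap)])
        return out
    if p.kind == "bent_cylinder":
        r, L, theta = d["radius"], d["length"], d["angle"]
        Rb = L / theta
        areas = np.array([2.0 * math.pi * r * L, math.pi * r**2, math.pi * r**2])
        comp = rng.choice(3, size=n, p=areas / areas.sum())
        out = np.empty((n, 3))

        def place(t, u, v):
            # local point at arc parameter t, in-plane offsets (u towards arc
            # centre, v lateral)
            x = Rb - (Rb - u) * np.cos(t)
            z = (Rb - u) * np.sin(t)
            return np.column_stack([x, v, z])

        lat = comp == 0
        n_lat = int(lat.sum())
        if n_lat:
            # area element on the tube wall ∝ (Rb − r cos φ): rejection-sample
            ts = np.empty(0)
            ps = np.empty(0)
            while len(ts) < n_lat:
                ct = rng.uniform(0.0, theta, 2 * n_lat)
                cp = rng.uniform(0.0, 2.0 * math.pi, 2 * n_lat)
                w = (Rb - r * np.cos(cp)) / (Rb + r)
                acc = rng.uniform(0.0, 1.0, 2 * n_lat) <= w
                ts = np.concatenate([ts, ct[acc]])
                ps = np.concatenate([ps, cp[acc]])
            ts, ps = ts[:n_lat], ps[:n_lat]
            out[lat] = place(ts, r * np.cos(ps), r * np.sin(ps))
        for which, t_cap in ((1, 0.0), (2, theta)):
            sel = comp == which
            k = int(sel.sum())
            if k:
                uv = _sample_disc(rng, k, r)
                out[sel] = place(np.full(k, t_cap), uv[:, 0], uv[:, 1])
        return out
    raise GeometryError(f"unknown primitive kind {p.kind!r}")  # pragma: no cover


def _punch_hole(points: np.ndarray, hole_fraction: float, rng) -> np.ndarray:
    """Remove a contiguous occlusion band of ``round(n·f)`` points.

    The band is a slab of randomly oriented normal through the middle of the
    cloud — the typical dropout of a ring-camera photogrammetry rig, where
    whole strips at poorly covered heights or in occlusion shadows fail to
    reconstruct while the silhouette extremes survive.
    """
    n_remove = int(round(len(points) * hole_fraction))
    if n_remove == 0:
        return points
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    proj = points @ direction
    dist = np.abs(proj - np.median(proj))
    keep = np.argsort(dist)[n_remove:]
    return points[np.sort(keep)]


def sample_surface(
    obj: "PrimitiveSpec | SyntheticBody",
    n_points: int,
    noise_sigma: float = 0.0,
    hole_fraction: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PointCloud, dict[str, np.ndarray]]:
    """Surface-sample a primitive or whole body into a world-frame point cloud.

    ``n_points`` applies per primitive (per segment for a body).  With
    ``noise_sigma = 0`` every point lies exactly on the generating surface;
    ``hole_fraction`` removes one contiguous occlusion-band patch of that
    fraction of the points (per primitive) before noise is added.
    Deterministic for a fixed ``seed``.  Returns the cloud and the posed
    landmarks.
    """
    if not (0.0 <= hole_fraction < 1.0):
        raise GeometryError(f"hole_fraction must be in [0, 1), got {hole_fraction}")
    if n_points < 4:
        raise GeometryError(f"need at least 4 points per primitive, got {n_points}")
    if rng is None:
        rng = np.random.default_rng(seed)

    if isinstance(obj, SyntheticBody):
        clouds = []
        landmarks = dict(obj.landmarks)
        for prim in obj.primitives.values():
            cloud, _ = sample_surface(prim, n_points, noise_sigma, hole_fraction, rng=rng)
            clouds.append(cloud.points)
        return PointCloud(np.vstack(clouds), frame="world"), landmarks

    local = _sample_primitive_surface(obj, n_points, rng)
    local = _punch_hole(local, hole_fraction, rng)
    pts = obj.pose.apply(local)
    if noise_sigma > 0:
        pts = pts + rng.normal(0.0, noise_sigma, pts.shape)
    return PointCloud(pts, frame="world"), obj.posed_landmarks()


# ---------------------------------------------------------------------------
# The default humanoid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticBody:
    """Primitives mapped to segment names, with landmarks and per-segment truth."""

    primitives: dict[str, PrimitiveSpec]
    landmarks: dict[str, np.ndarray]
    true_properties: dict[str, InertialProperties]
    total_mass: float

    def segmentation(self) -> BodySegmentation:
        return default_segmentation(self.landmarks)

    def true_total(self) -> InertialProperties:
        return combine_properties(list(self.true_properties.values()))

    def sample(self, n_points_per_segment: int, noise_sigma: float = 0.0,
               hole_fraction: float = 0.0, seed: int | None = None):
        return sample_surface(self, n_points_per_segment, noise_sigma,
                              hole_fraction, seed=seed)


def _pose(translation, rotation: np.ndarray | None = None) -> RigidTransform:
    R = np.eye(3) if rotation is None else rotation
    return RigidTransform(R, np.asarray(translation, dtype=float))


_RX_PI = np.diag([1.0, -1.0, -1.0])          # point local +z downward
_RY_90 = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])  # +z → +x


def generate_default_humanoid(
    height: float,
    total_mass: float,
    seed: int | None = None,
    bent_limbs: bool = False,
) -> SyntheticBody:
    """Standing humanoid of posed primitives whose true masses sum to ``total_mass``.

    Fourteen segments — head, trunk and left/right upper arm, forearm, hand,
    thigh, shank and foot, the decomposition the default segmentation reports —
    posed in the standard anatomical standing pose with hanging arms held
    laterally clear of the trunk so landmark-defined planes separate every
    segment.  All proportions scale with ``height``; densities start at the
    trunk/uniform defaults (940 / 1000 kg/m³) and are then rescaled by one
    common factor so the exact segment masses sum to ``total_mass``.

    With ``bent_limbs=True`` the shanks and forearms become volume-preserving
    bent cylinders (concave), emulating natural limb curvature; their stored
    "true" inertia comes from the voxel oracle and is approximate.

    The geometry is fully deterministic; ``seed`` is accepted for signature
    symmetry with the samplers and is unused here.
    """
    del seed  # geometry is deterministic
    if height <= 0 or total_mass <= 0:
        raise GeometryError("height and total_mass must be positive")
    H = height

    lms: dict[str, np.ndarray] = {
        "floor": (0.0, 0.0, 0.0),
        "vertex": (0.0, 0.0, 1.0 * H),
        "neck": (0.0, 0.0, 0.88 * H),
        "pelvis": (0.0, 0.0, 0.52 * H),
    }
    for p, sgn in (("l", -1.0), ("r", 1.0)):
        lms[f"{p}_shoulder"] = (0.0, sgn * 0.20 * H, 0.84 * H)
        lms[f"{p}_armpit"] = (0.0, sgn * 0.155 * H, 0.84 * H)
        lms[f"{p}_elbow"] = (0.0, sgn * 0.20 * H, 0.63 * H)
        lms[f"{p}_wrist"] = (0.0, sgn * 0.20 * H, 0.46 * H)
        lms[f"{p}_hand_tip"] = (0.0, sgn * 0.20 * H, 0.355 * H)
        lms[f"{p}_hip"] = (0.0, sgn * 0.07 * H, 0.52 * H)
        lms[f"{p}_knee"] = (0.0, sgn * 0.07 * H, 0.285 * H)
        lms[f"{p}_ankle"] = (0.0, sgn * 0.07 * H, 0.06 * H)
        lms[f"{p}_heel"] = (-0.045 * H, sgn * 0.07 * H, 0.028 * H)
        lms[f"{p}_toe"] = (0.115 * H, sgn * 0.07 * H, 0.028 * H)
    landmarks = {k: np.asarray(v, dtype=float) for k, v in lms.items()}

    prims: dict[str, PrimitiveSpec] = {
        "head": PrimitiveSpec(
            "sphere", {"radius": 0.055 * H}, _pose([0, 0, 0.945 * H]),
        ),
        "trunk": PrimitiveSpec(
            "ellipsoid", {"a": 0.09 * H, "b": 0.13 * H, "c": 0.18 * H},
            _pose([0, 0, 0.70 * H]), density=TRUNK_DENSITY,
        ),
    }
    for p, side, sgn in (("l", "left", -1.0), ("r", "right", 1.0)):
        y_arm, y_leg = sgn * 0.20 * H, sgn * 0.07 * H
        prims[f"{side}_upper_arm"] = PrimitiveSpec(
            "truncated_cone",
            {"r_base": 0.042 * H, "r_top": 0.034 * H, "length": 0.204 * H},
            _pose([0, y_arm, 0.837 * H], _RX_PI),
        )
        if bent_limbs:
            theta = math.radians(30.0)
            bend = RigidTransform.from_rotation_about([0, 1, 0], -theta / 2.0)
            prims[f"{side}_forearm"] = PrimitiveSpec(
                "bent_cylinder",
                {"radius": 0.030 * H, "length": 0.155 * H, "angle": theta},
                _pose([0, y_arm, 0.627 * H], _RX_PI).compose(bend),
            )
        else:
            prims[f"{side}_forearm"] = PrimitiveSpec(
                "truncated_cone",
                {"r_base": 0.034 * H, "r_top": 0.026 * H, "length": 0.164 * H},
                _pose([0, y_arm, 0.627 * H], _RX_PI),
            )
        prims[f"{side}_hand"] = PrimitiveSpec(
            "ellipsoid", {"a": 0.025 * H, "b": 0.025 * H, "c": 0.05 * H},
            _pose([0, y_arm, 0.405 * H]),
        )
        prims[f"{side}_thigh"] = PrimitiveSpec(
            "truncated_cone",
            {"r_base": 0.065 * H, "r_top": 0.048 * H, "length": 0.229 * H},
            _pose([0, y_leg, 0.517 * H], _RX_PI),
        )
        if bent_limbs:
            theta = math.radians(35.0)
            bend = RigidTransform.from_rotation_about([0, 1, 0], -theta / 2.0)
            prims[f"{side}_shank"] = PrimitiveSpec(
                "bent_cylinder",
                {"radius": 0.038 * H, "length": 0.20 * H, "angle": theta},
                _pose([0, y_leg, 0.282 * H], _RX_PI).compose(bend),
            )
        else:
            prims[f"{side}_shank"] = PrimitiveSpec(
                "truncated_cone",
                {"r_base": 0.046 * H, "r_top": 0.030 * H, "length": 0.219 * H},
                _pose([0, y_leg, 0.282 * H], _RX_PI),
            )
        prims[f"{side}_foot"] = PrimitiveSpec(
            "cylinder", {"radius": 0.028 * H, "length": 0.16 * H},
            _pose([-0.045 * H, y_leg, 0.028 * H], _RY_90),
        )

    props = {name: analytic_properties(p) for name, p in prims.items()}
    raw_total = sum(p.mass for p in props.values())
    f = total_mass / raw_total  # common density rescale: exact mass closure
    prims = {
        name: replace(p, dimensions=p.dimensions, density=p.density * f)
        for name, p in prims.items()
    }
    props = {
        name: replace(p, mass=p.mass * f, inertia_com=p.inertia_com * f)
        for name, p in props.items()
    }
    return SyntheticBody(
        primitives=prims,
        landmarks=landmarks,
        true_properties=props,
        total_mass=float(total_mass),
    )
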