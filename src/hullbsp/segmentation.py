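"""Anatomical segmentation of a whole-body surface point cloud.

A scanned cloud is first brought into a metric, upright ``world`` frame
(uniform scale + rotation + translation from a known landmark distance), then
partitioned into body segments by half-spaces whose cutting planes are defined
entirely by named landmarks: a landmark on the plane plus a landmark pair
giving the normal direction.  Each segment finally gets a right-handed
anatomical frame with its longitudinal axis running proximal → distal (z by
convention, x for the foot), in which the CoM is reported as a percentage of
segment length.

Coordinate convention (standing anatomical pose): +z vertical (cranial),
x anterior, y lateral; right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .mesh_core import (
    DegenerateGeometryError,
    GeometryError,
    InertialProperties,
    PointCloud,
    RigidTransform,
)

__all__ = [
    "InsufficientPointsError",
    "Landmark",
    "CutPlane",
    "SegmentSpec",
    "BodySegmentation",
    "scale_and_orient",
    "cut_by_planes",
    "segment_frame",
    "relative_com",
    "default_segmentation",
    "TRUNK_DENSITY",
    "UNIFORM_DENSITY",
]

# Segment densities in kg/m³.  The trunk value is deliberately lower than
# soft-tissue density to account for the air volume of the lungs enclosed by a
# surface scan; all other segments use a uniform soft-tissue value.
TRUNK_DENSITY = 940.0
UNIFORM_DENSITY = 1000.0


class InsufficientPointsError(GeometryError):
    """A segment received too few (or only coplanar) points to hull."""


@dataclass(frozen=True)
class Landmark:
    name: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise GeometryError(f"landmark {self.name!r} has non-finite coordinates")
        object.__setattr__(self, "position", pos)


LandmarkSet = Mapping[str, np.ndarray]


def _landmark_dict(landmarks) -> dict[str, np.ndarray]:
    if isinstance(landmarks, Mapping):
        return {k: np.asarray(v, dtype=float).reshape(3) for k, v in landmarks.items()}
    out: dict[str, np.ndarray] = {}
    for lm in landmarks:
        if lm.name in out:
            raise GeometryError(f"duplicate landmark name {lm.name!r}")
        out[lm.name] = lm.position
    return out


@dataclass(frozen=True)
class CutPlane:
    """Half-space constraint: keep points with ``side · (p − origin)·n̂ ≥ 0``.

    ``origin`` names the landmark on the plane; ``normal`` is a landmark pair
    (from, to) whose difference vector, normalised, gives the plane normal.
    """

    origin: str
    normal: tuple[str, str]
    side: int = 1

    def __post_init__(self):
        if self.side not in (1, -1):
            raise GeometryError(f"plane side must be +1 or -1, got {self.side}")

    def signed_distance(self, points: np.ndarray, landmarks: LandmarkSet) -> np.ndarray:
        o = np.asarray(landmarks[self.origin], dtype=float)
        a = np.asarray(landmarks[self.normal[0]], dtype=float)
        b = np.asarray(landmarks[self.normal[1]], dtype=float)
        n = b - a
        norm = np.linalg.norm(n)
        if norm == 0:
            raise DegenerateGeometryError(
                f"plane normal landmarks {self.normal} coincide"
            )
        return self.side * ((points - o) @ (n / norm))


@dataclass(frozen=True)
class SegmentSpec:
    """One anatomical segment: density, cutting planes and axis endpoints."""

    name: str
    side: str = "central"  # left | right | central
    density: float = UNIFORM_DENSITY
    planes: tuple[CutPlane, ...] = ()
    proximal: str = ""
    distal: str = ""
    longitudinal_axis: str = "z"  # "z" by convention; "x" for the foot

    def __post_init__(self):
        object.__setattr__(self, "planes", tuple(self.planes))
        if not (self.density > 0):
            raise GeometryError(f"segment {self.name!r}: density must be > 0")
        if self.side not in ("left", "right", "central"):
            raise GeometryError(f"segment {self.name!r}: side must be left/right/central")
        if self.longitudinal_axis not in ("x", "z"):
            raise GeometryError(f"segment {self.name!r}: axis must be 'x' or 'z'")
        if self.proximal and self.proximal == self.distal:
            raise GeometryError(f"segment {self.name!r}: proximal equals distal landmark")


@dataclass(frozen=True)
class BodySegmentation:
    """Ordered segment specs plus the landmark set they reference.

    Segment order matters: points satisfying several segments' half-spaces
    (only possible exactly on a shared cutting plane) go to the first match,
    so specs are listed proximal-first — the tie rule that a boundary point
    belongs to the more axial/cranial segment.
    """

    segments: tuple[SegmentSpec, ...]
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "landmarks", _landmark_dict(self.landmarks))
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise GeometryError("segment names must be unique")
        for seg in self.segments:
            referenced = [seg.proximal, seg.distal] if seg.proximal else []
            for pl in seg.planes:
                referenced += [pl.origin, pl.normal[0], pl.normal[1]]
            missing = [r for r in referenced if r and r not in self.landmarks]
            if missing:
                raise GeometryError(
                    f"segment {seg.name!r} references unknown landmarks: {missing}"
                )

    def __getitem__(self, name: str) -> SegmentSpec:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "landmarks": {k: [float(x) for x in v] for k, v in self.landmarks.items()},
            "segments": [
                {
                    "name": s.name,
                    "side": s.side,
                    "density_kg_m3": s.density,
                    "proximal": s.proximal,
                    "distal": s.distal,
                    "axis": s.longitudinal_axis,
                    "planes": [
                        {"origin": p.origin, "normal": list(p.normal), "side": p.side}
                        for p in s.planes
                    ],
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "BodySegmentation":
        segments = tuple(
            SegmentSpec(
                name=s["name"],
                side=s.get("side", "central"),
                density=float(s.get("density_kg_m3", UNIFORM_DENSITY)),
                planes=tuple(
                    CutPlane(p["origin"], (p["normal"][0], p["normal"][1]),
                             int(p.get("side", 1)))
                    for p in s.get("planes", [])
                ),
                proximal=s.get("proximal", ""),
                distal=s.get("distal", ""),
                longitudinal_axis=s.get("axis", "z"),
            )
            for s in data["segments"]
        )
        return cls(segments=segments, landmarks=data.get("landmarks", {}))


# ---------------------------------------------------------------------------
# Scaling and orientation
# ---------------------------------------------------------------------------

def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u to unit vector v (Rodrigues)."""
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def scale_and_orient(
    cloud: PointCloud,
    landmarks,
    reference_pair: tuple[str, str],
    reference_distance: float,
    up_pair: tuple[str, str] | None = None,
) -> tuple[PointCloud, dict[str, np.ndarray], tuple[float, np.ndarray, np.ndarray]]:
    """Bring a raw cloud into the metric upright world frame.

    One similarity transform ``p ↦ s R p + t`` is applied to the cloud and its
    landmarks such that the ``reference_pair`` landmarks end up exactly
    ``reference_distance`` metres apart (e.g. a head–floor pair at the measured
    subject height) and the ``up_pair`` direction (low, high) becomes +z, with
    the low landmark at the origin.  Returns the transformed cloud, transformed
    landmarks, and the ``(s, R, t)`` triple.
    """
    lms = _landmark_dict(landmarks)
    if reference_distance <= 0:
        raise GeometryError("reference distance must be positive")
    a, b = (lms[reference_pair[0]], lms[reference_pair[1]])
    raw_dist = np.linalg.norm(b - a)
    if raw_dist == 0:
        raise DegenerateGeometryError(
            f"reference landmarks {reference_pair} coincide"
        )
    scale = reference_distance / raw_dist

    if up_pair is None:
        up_pair = reference_pair
    lo, hi = lms[up_pair[0]], lms[up_pair[1]]
    up = hi - lo
    if np.linalg.norm(up) == 0:
        raise DegenerateGeometryError(f"up-hint landmarks {up_pair} coincide")
    R = _rotation_between(up / np.linalg.norm(up), np.array([0.0, 0.0, 1.0]))
    t = -scale * R @ lo

    new_points = scale * (cloud.points @ R.T) + t
    new_lms = {k: scale * (R @ v) + t for k, v in lms.items()}
    return PointCloud(new_points, frame="world"), new_lms, (scale, R, t)


# ---------------------------------------------------------------------------
# Plane cutting
# ---------------------------------------------------------------------------

def cut_by_planes(cloud: PointCloud, seg: BodySegmentation) -> dict[str, PointCloud]:
    """Partition a world-frame cloud into per-segment clouds.

    Every point lands in exactly one segment: the first (most proximal) spec
    whose half-space constraints it satisfies, boundary points included
    (``≥ 0``).  Points satisfying no segment — possible only when the config's
    half-spaces do not cover space — are assigned to the segment they violate
    least, keeping the partition total.  A segment ending up with fewer than
    four non-coplanar points raises :class:`InsufficientPointsError`.
    """
    pts = cloud.points
    n = len(pts)
    assignment = np.full(n, -1, dtype=np.int64)
    worst = np.full((n, len(seg.segments)), np.inf)
    for j, spec in enumerate(seg.segments):
        dmin = np.full(n, np.inf)
        for plane in spec.planes:
            dmin = np.minimum(dmin, plane.signed_distance(pts, seg.landmarks))
        worst[:, j] = dmin
        take = (assignment < 0) & (dmin >= 0)
        assignment[take] = j
    leftover = assignment < 0
    if leftover.any():
        assignment[leftover] = np.argmax(worst[leftover], axis=1)

    out: dict[str, PointCloud] = {}
    for j, spec in enumerate(seg.segments):
        sub = pts[assignment == j]
        if len(sub) < 4 or np.linalg.matrix_rank(sub - sub.mean(axis=0), tol=1e-12) < 3:
            raise InsufficientPointsError(
                f"segment {spec.name!r} received {len(sub)} usable points; "
                "need at least 4 non-coplanar"
            )
        out[spec.name] = PointCloud(sub, frame="world")
    return out


# ---------------------------------------------------------------------------
# Segment anatomical frames
# ---------------------------------------------------------------------------

def segment_frame(
    segment_cloud: PointCloud | None,
    spec: SegmentSpec,
    landmarks,
) -> RigidTransform:
    """Rigid world → segment-anatomical transform for one segment.

    In the returned frame the origin sits at the proximal landmark and the
    longitudinal axis (+z, or +x for the foot) points from the proximal to the
    distal landmark.  The remaining axes complete a right-handed basis keyed to
    the world anterior (x) / vertical (z) directions so the frame is stable
    for near-vertical segments.
    """
    lms = _landmark_dict(landmarks)
    prox, dist = lms[spec.proximal], lms[spec.distal]
    u = dist - prox
    length = np.linalg.norm(u)
    if length == 0:
        raise DegenerateGeometryError(
            f"segment {spec.name!r}: proximal and distal landmarks coincide"
        )
    u = u / length

    if spec.longitudinal_axis == "z":
        ref = np.array([1.0, 0.0, 0.0])  # world anterior
        if abs(np.dot(ref, u)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, u) * u
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        R = np.vstack([e1, e2, u])  # rows: segment x, y, z in world coords
    else:  # foot: longitudinal +x
        ref = np.array([0.0, 0.0, 1.0])  # world vertical becomes segment z
        if abs(np.dot(ref, u)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e3 = ref - np.dot(ref, u) * u
        e3 /= np.linalg.norm(e3)
        e2 = np.cross(e3, u)
        R = np.vstack([u, e2, e3])
    return RigidTransform(R, -R @ prox)


def relative_com(
    props: InertialProperties,
    spec: SegmentSpec,
    landmarks,
) -> tuple[float, float, float]:
    """CoM position as percentages of segment length, from the proximal landmark.

    ``props`` must be expressed in the segment-anatomical frame (proximal
    landmark at the origin, longitudinal axis +z or +x).  Returns
    ``(longitudinal %, transverse shift % first off-axis, second off-axis)``;
    for z-axis segments the transverse components are (x, y), for the foot
    (y, z).
    """
    lms = _landmark_dict(landmarks)
    length = float(np.linalg.norm(lms[spec.distal] - lms[spec.proximal]))
    if length == 0:
        raise DegenerateGeometryError(f"segment {spec.name!r} has zero length")
    com = props.com
    if spec.longitudinal_axis == "z":
        axis, t1, t2 = 2, 0, 1
    else:
        axis, t1, t2 = 0, 1, 2
    return (
        100.0 * com[axis] / length,
        100.0 * com[t1] / length,
        100.0 * com[t2] / length,
    )


# ---------------------------------------------------------------------------
# Default segmentation
# ---------------------------------------------------------------------------

# Landmark names the default configuration expects (generated by
# synthetic_body.generate_default_humanoid, or supplied by the user for a real
# scan). Lateral cut planes between the arms and trunk use the armpit
# landmarks; the shoulder pair supplies the lateral (y) normal, the neck–pelvis
# pair the vertical (z) normal.
DEFAULT_LANDMARK_NAMES = (
    "vertex", "neck", "pelvis",
    "l_shoulder", "r_shoulder", "l_armpit", "r_armpit",
    "l_elbow", "r_elbow", "l_wrist", "r_wrist", "l_hand_tip", "r_hand_tip",
    "l_hip", "r_hip", "l_knee", "r_knee", "l_ankle", "r_ankle",
    "l_heel", "r_heel", "l_toe", "r_toe",
)


def default_segmentation(landmarks) -> BodySegmentation:
    """The 14-segment decomposition reported for standing whole-body scans.

    Head, trunk and left/right upper arm, forearm, hand, thigh, shank, foot —
    cut by horizontal joint planes plus lateral armpit planes separating the
    hanging arms from the trunk, with the trunk at 940 kg/m³ and all other
    segments at 1000 kg/m³.  Specs are ordered proximal-first so boundary
    points resolve to the more axial segment.
    """
    lms = _landmark_dict(landmarks)
    missing = [n for n in DEFAULT_LANDMARK_NAMES if n not in lms]
    if missing:
        raise GeometryError(f"default segmentation needs landmarks: {missing}")

    Y = ("l_shoulder", "r_shoulder")   # normal pointing left → right (+y)
    Z = ("pelvis", "neck")             # normal pointing caudal → cranial (+z)

    def arm_side(prefix):
        # lateral of the armpit plane on that side
        side = -1 if prefix == "l" else 1
        return CutPlane(f"{prefix}_armpit", Y, side)

    def leg_side(prefix):
        side = -1 if prefix == "l" else 1
        return CutPlane("pelvis", Y, side)

    segments: list[SegmentSpec] = [
        SegmentSpec(
            "head", "central", UNIFORM_DENSITY,
            planes=(CutPlane("neck", Z, 1),),
            proximal="neck", distal="vertex",
        ),
        SegmentSpec(
            "trunk", "central", TRUNK_DENSITY,
            planes=(
                CutPlane("neck", Z, -1),
                CutPlane("pelvis", Z, 1),
                CutPlane("l_armpit", Y, 1),
                CutPlane("r_armpit", Y, -1),
            ),
            proximal="neck", distal="pelvis",
        ),
    ]
    for p, side in (("l", "left"), ("r", "right")):
        up_elbow = (f"{p}_elbow", f"{p}_shoulder")   # normal distal → proximal
        wrist_up = (f"{p}_wrist", f"{p}_elbow")
        segments += [
            SegmentSpec(
                f"{side}_upper_arm", side, UNIFORM_DENSITY,
                planes=(arm_side(p), CutPlane(f"{p}_elbow", up_elbow, 1)),
                proximal=f"{p}_shoulder", distal=f"{p}_elbow",
            ),
            SegmentSpec(
                f"{side}_forearm", side, UNIFORM_DENSITY,
                planes=(arm_side(p), CutPlane(f"{p}_elbow", up_elbow, -1),
                        CutPlane(f"{p}_wrist", wrist_up, 1)),
                proximal=f"{p}_elbow", distal=f"{p}_wrist",
            ),
            SegmentSpec(
                f"{side}_hand", side, UNIFORM_DENSITY,
                planes=(arm_side(p), CutPlane(f"{p}_wrist", wrist_up, -1)),
                proximal=f"{p}_wrist", distal=f"{p}_hand_tip",
            ),
        ]
    for p, side in (("l", "left"), ("r", "right")):
        knee_up = (f"{p}_knee", f"{p}_hip")
        ankle_up = (f"{p}_ankle", f"{p}_knee")
        segments += [
            SegmentSpec(
                f"{side}_thigh", side, UNIFORM_DENSITY,
                planes=(leg_side(p), CutPlane("pelvis", Z, -1),
                        CutPlane(f"{p}_knee", knee_up, 1)),
                proximal=f"{p}_hip", distal=f"{p}_knee",
            ),
            SegmentSpec(
                f"{side}_shank", side, UNIFORM_DENSITY,
                planes=(leg_side(p), CutPlane(f"{p}_knee", knee_up, -1),
                        CutPlane(f"{p}_ankle", ankle_up, 1)),
                proximal=f"{p}_knee", distal=f"{p}_ankle",
            ),
            SegmentSpec(
                f"{side}_foot", side, UNIFORM_DENSITY,
                planes=(leg_side(p), CutPlane(f"{p}_ankle", ankle_up, -1)),
                proximal=f"{p}_heel", distal=f"{p}_toe",
                longitudinal_axis="x",
            ),
        ]
    return BodySegmentation(segments=tuple(segments), landmarks=lms)
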