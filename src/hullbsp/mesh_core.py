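"""Geometry kernel: convex hulls, exact polyhedral mass properties, rigid-transform algebra.

All quantities are SI internally: metres, kilograms, kg·m². The inertia tensor
convention is ``I = ∫ ρ (‖r‖² Id − r rᵀ) dV`` about the centre of mass, so the
products of inertia are the (signed) off-diagonal entries, e.g.
``Ixy = −∫ ρ x y dV``.  Report layers may additionally emit unsigned magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "GeometryError",
    "DegenerateGeometryError",
    "MeshValidationError",
    "InvalidTransformError",
    "FrameMismatchError",
    "EmptyInputError",
    "PointCloud",
    "TriangleMesh",
    "RigidTransform",
    "InertialProperties",
    "MeshValidationReport",
    "convex_hull",
    "mass_properties",
    "transform_properties",
    "combine_properties",
    "validate_mesh",
]

_ORTHO_TOL = 1e-8


class GeometryError(ValueError):
    """Base class for geometric input errors."""


class DegenerateGeometryError(GeometryError):
    """Point set is too small or too flat to bound a volume (coplanar/collinear)."""


class MeshValidationError(GeometryError):
    """Mesh is not watertight, inconsistently wound, or inside-out."""


class InvalidTransformError(GeometryError):
    """Rotation matrix is not a proper orthonormal rotation."""


class FrameMismatchError(GeometryError):
    """Operands are expressed in different coordinate frames."""


class EmptyInputError(GeometryError):
    """An operation received an empty collection."""


def _as_points(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        arr = arr.reshape(0, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise GeometryError(f"expected an (n, 3) array of points, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError("points contain non-finite coordinates")
    return arr


@dataclass(frozen=True)
class PointCloud:
    """Unordered 3D surface samples in metres, tagged with a frame label.

    ``frame`` is free-form; the conventional labels are ``raw`` (scanner
    output, arbitrary units), ``world`` (metres, +z vertical) and
    ``segment`` (per-segment anatomical frame).
    """

    points: np.ndarray
    frame: str = "raw"

    def __post_init__(self):
        object.__setattr__(self, "points", _as_points(self.points))

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, xf: "RigidTransform", frame: str | None = None) -> "PointCloud":
        return PointCloud(xf.apply(self.points), frame if frame is not None else self.frame)


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle surface mesh; faces wound so normals point outward."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "vertices", _as_points(self.vertices))
        faces = np.asarray(self.faces, dtype=np.int64)
        if faces.size == 0:
            faces = faces.reshape(0, 3)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise GeometryError(f"faces must be (m, 3) vertex-index triples, got {faces.shape}")
        if faces.size and (faces.min() < 0 or faces.max() >= len(self.vertices)):
            raise GeometryError("face indices out of range")
        object.__setattr__(self, "faces", faces)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p ↦ R p + t`` (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidTransformError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise InvalidTransformError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise InvalidTransformError("rotation matrix has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotation_about(cls, axis, angle_rad: float, origin=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle_rad`` about ``axis`` through ``origin`` (Rodrigues)."""
        k = np.asarray(axis, dtype=float)
        k = k / np.linalg.norm(k)
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        o = np.asarray(origin, dtype=float)
        return cls(R, o - R @ o)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class InertialProperties:
    """Volume, mass, CoM and inertia tensor about the CoM in a stated frame."""

    volume: float
    mass: float
    com: np.ndarray
    inertia_com: np.ndarray
    frame: str = "world"

    def __post_init__(self):
        object.__setattr__(self, "com", np.asarray(self.com, dtype=float).reshape(3))
        I = np.asarray(self.inertia_com, dtype=float)
        if I.shape != (3, 3):
            raise GeometryError(f"inertia tensor must be 3x3, got {I.shape}")
        object.__setattr__(self, "inertia_com", I)
        if not (self.volume > 0):
            raise GeometryError(f"volume must be positive, got {self.volume}")
        if not (self.mass > 0):
            raise GeometryError(f"mass must be positive, got {self.mass}")

    def principal_moments(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.inertia_com)

    def is_realisable(self, rtol: float = 1e-6) -> bool:
        """Symmetric, PSD, and each principal moment ≤ sum of the other two."""
        I = self.inertia_com
        scale = max(np.abs(I).max(), 1e-300)
        if not np.allclose(I, I.T, atol=rtol * scale):
            return False
        ev = np.linalg.eigvalsh(0.5 * (I + I.T))
        if ev.min() < -rtol * scale:
            return False
        return bool(np.all(ev <= ev.sum() - ev + rtol * scale))

    def scaled(self, factor: float) -> "InertialProperties":
        """Multiply mass, volume and the full inertia tensor by ``factor`` (density rescale)."""
        return replace(
            self,
            volume=self.volume * factor,
            mass=self.mass * factor,
            inertia_com=self.inertia_com * factor,
        )


# ---------------------------------------------------------------------------
# Convex hulls
# ---------------------------------------------------------------------------

def convex_hull(cloud: PointCloud | np.ndarray) -> TriangleMesh:
    """Minimum convex hull of a point cloud as a watertight, outward-wound mesh.

    Robust to interior points and to holes in the surface sampling.  Degenerate
    input (fewer than four points, or all points coplanar/collinear) raises
    :class:`DegenerateGeometryError` rather than returning a zero-volume shell.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else _as_points(cloud)
    if len(pts) < 4:
        raise DegenerateGeometryError(
            f"convex hull needs at least 4 points, got {len(pts)}"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(
            "degenerate point cloud (coplanar or collinear); cannot bound a volume"
        ) from exc
    # Re-index to hull vertices only and wind every face outward.
    remap = np.full(len(pts), -1, dtype=np.int64)
    remap[hull.vertices] = np.arange(len(hull.vertices))
    vertices = pts[hull.vertices]
    faces = remap[hull.simplices]
    centre = vertices.mean(axis=0)
    a, b, c = (vertices[faces[:, k]] for k in range(3))
    normals = np.cross(b - a, c - a)
    flip = np.einsum("ij,ij->i", normals, a - centre) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return TriangleMesh(vertices, faces)


# ---------------------------------------------------------------------------
# Mesh validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeshValidationReport:
    """Combinatorial soundness report; never raises."""

    watertight: bool
    consistent_orientation: bool
    signed_volume: float
    boundary_edge_count: int

    @property
    def ok(self) -> bool:
        return self.watertight and self.consistent_orientation and self.signed_volume > 0


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    if len(faces) == 0:
        return 0.0
    v = vertices - vertices.mean(axis=0)  # conditioning only; result origin-invariant
    a, b, c = v[faces[:, 0]], v[faces[:, 1]], v[faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def validate_mesh(mesh: TriangleMesh) -> MeshValidationReport:
    """Check two-manifold closure and coherent winding; report signed volume.

    The check is exact and combinatorial (edge–face incidence counts), with no
    geometric epsilon: a watertight mesh has every undirected edge shared by
    exactly two faces, and coherent winding means the two incident faces
    traverse the shared edge in opposite directions.
    """
    faces = mesh.faces
    directed: dict[tuple[int, int], int] = {}
    undirected: dict[tuple[int, int], int] = {}
    for tri in faces:
        for i in range(3):
            e = (int(tri[i]), int(tri[(i + 1) % 3]))
            directed[e] = directed.get(e, 0) + 1
            u = (min(e), max(e))
            undirected[u] = undirected.get(u, 0) + 1
    watertight = len(faces) > 0 and all(n == 2 for n in undirected.values())
    consistent = len(faces) > 0 and all(n == 1 for n in directed.values())
    if watertight and consistent:
        # both directions must be present for every edge
        consistent = all((e[1], e[0]) in directed for e in directed)
    boundary = sum(1 for n in undirected.values() if n == 1)
    return MeshValidationReport(
        watertight=watertight,
        consistent_orientation=consistent,
        signed_volume=_signed_volume(mesh.vertices, faces),
        boundary_edge_count=boundary,
    )


# ---------------------------------------------------------------------------
# Polyhedral mass properties
# ---------------------------------------------------------------------------

def mass_properties(mesh: TriangleMesh, density: float, frame: str = "world") -> InertialProperties:
    """Exact volume, CoM and inertia tensor of a watertight mesh at uniform density.

    Decomposes the polyhedron into signed tetrahedra against an apex point and
    accumulates the exact polynomial integrals ``∫dV``, ``∫x dV`` and
    ``∫x_i x_j dV`` per tetrahedron; the inertia is then moved to the centre of
    mass by the parallel-axis theorem.  The mesh is pre-translated to its
    vertex centroid before integration (and results translated back) so the
    output is origin-invariant to round-off.
    """
    if not (density > 0):
        raise GeometryError(f"density must be positive, got {density}")
    report = validate_mesh(mesh)
    if not report.watertight:
        raise MeshValidationError(
            f"mesh is not watertight ({report.boundary_edge_count} boundary edges)"
        )
    if not report.consistent_orientation:
        raise MeshValidationError("mesh faces are inconsistently wound")
    if report.signed_volume <= 0:
        raise MeshValidationError(
            f"mesh signed volume is {report.signed_volume:.3g}; faces point inward"
        )

    shift = mesh.vertices.mean(axis=0)
    v = mesh.vertices - shift
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    det = np.einsum("ij,ij->i", a, np.cross(b, c))  # 6 × signed tet volume

    volume = det.sum() / 6.0
    first = (det[:, None] * (a + b + c)).sum(axis=0) / 24.0  # ∫ x dV
    com_local = first / volume

    # ∫ x_i x_j dV per tet with apex at origin:
    #   (det/120) [ (a+b+c)(a+b+c)ᵀ + a aᵀ + b bᵀ + c cᵀ ]
    s = a + b + c
    C = (
        np.einsum("k,ki,kj->ij", det, s, s)
        + np.einsum("k,ki,kj->ij", det, a, a)
        + np.einsum("k,ki,kj->ij", det, b, b)
        + np.einsum("k,ki,kj->ij", det, c, c)
    ) / 120.0
    C = 0.5 * (C + C.T)

    mass = density * volume
    inertia_origin = density * (np.trace(C) * np.eye(3) - C)
    d = com_local
    inertia_com = inertia_origin - mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))
    inertia_com = 0.5 * (inertia_com + inertia_com.T)

    return InertialProperties(
        volume=float(volume),
        mass=float(mass),
        com=com_local + shift,
        inertia_com=inertia_com,
        frame=frame,
    )


def transform_properties(props: InertialProperties, xf: RigidTransform,
                         frame: str | None = None) -> InertialProperties:
    """Re-express inertial properties under a rigid transform.

    The CoM maps as a point; the CoM-frame inertia tensor rotates as
    ``R I Rᵀ`` and is invariant under pure translation.  Mass and volume are
    unchanged.
    """
    R = xf.rotation
    return InertialProperties(
        volume=props.volume,
        mass=props.mass,
        com=xf.apply(props.com),
        inertia_com=R @ props.inertia_com @ R.T,
        frame=frame if frame is not None else props.frame,
    )


def combine_properties(parts: Sequence[InertialProperties]) -> InertialProperties:
    """Rigidly compose parts into one body (sums + parallel-axis recombination).

    Mass and volume add; the CoM is the mass-weighted mean; each part's inertia
    is shifted from its own CoM to the combined CoM by the full parallel-axis
    theorem (off-diagonal terms included) and summed.
    """
    parts = list(parts)
    if not parts:
        raise EmptyInputError("cannot combine an empty list of parts")
    frames = {p.frame for p in parts}
    if len(frames) > 1:
        raise FrameMismatchError(f"parts are in different frames: {sorted(frames)}")
    mass = sum(p.mass for p in parts)
    volume = sum(p.volume for p in parts)
    com = sum(p.mass * p.com for p in parts) / mass
    inertia = np.zeros((3, 3))
    for p in parts:
        d = p.com - com
        inertia += p.inertia_com + p.mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))
    return InertialProperties(volume=float(volume), mass=float(mass), com=com,
                              inertia_com=inertia, frame=parts[0].frame)
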