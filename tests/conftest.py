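"""Shared fixtures: reference solids and independent numeric oracles.

The Monte-Carlo mass-property integrator and the exact convex-polytope plane
clipper defined here are deliberately independent of the package's polyhedral
integration path: they are the oracles the implementation is checked against.
"""

import numpy as np
import pytest

from hullbsp import PointCloud, TriangleMesh, convex_hull


@pytest.fixture
def unit_cube_cloud() -> PointCloud:
    corners = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    return PointCloud(corners, frame="world")


@pytest.fixture
def unit_cube_mesh(unit_cube_cloud) -> TriangleMesh:
    return convex_hull(unit_cube_cloud)


@pytest.fixture
def make_polytope():
    """Factory: convex hull of ``n`` Gaussian points at a given seed and scale."""

    def _make(seed: int, n: int = 30, scale: float = 1.0, offset=(0.0, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3)) * scale + np.asarray(offset, dtype=float)
        return convex_hull(PointCloud(pts))

    return _make


def _face_halfspaces(mesh: TriangleMesh):
    """Outward face normals and offsets of a convex mesh: inside ⇔ n·p ≤ b."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    n = np.cross(b - a, c - a)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return n, np.einsum("ij,ij->i", n, a)


def mc_mass_properties(mesh: TriangleMesh, density: float, n_samples: int,
                       seed: int = 0):
    """Monte-Carlo rejection-sampling integrator for a CONVEX mesh.

    Samples uniformly in the bounding box and keeps points inside every face
    half-space.  Returns (volume, com, inertia_about_com, n_inside).  Standard
    errors scale as 1/sqrt(n_inside).
    """
    rng = np.random.default_rng(seed)
    normals, offsets = _face_halfspaces(mesh)
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    box_vol = float(np.prod(hi - lo))

    n_in = 0
    first = np.zeros(3)
    second = np.zeros((3, 3))
    chunk = 200_000
    remaining = n_samples
    while remaining > 0:
        k = min(chunk, remaining)
        remaining -= k
        p = rng.uniform(lo, hi, size=(k, 3))
        inside = np.all(p @ normals.T <= offsets + 1e-12, axis=1)
        q = p[inside]
        n_in += len(q)
        first += q.sum(axis=0)
        second += q.T @ q
    volume = box_vol * n_in / n_samples
    mass = density * volume
    com = first / n_in
    I_origin = density * (box_vol / n_samples) * (
        np.trace(second) * np.eye(3) - second
    )
    I_com = I_origin - mass * (np.dot(com, com) * np.eye(3) - np.outer(com, com))
    return volume, com, 0.5 * (I_com + I_com.T), n_in


def clip_convex_mesh(mesh: TriangleMesh, axis: int, cut: float):
    """Exactly clip a convex mesh by the plane ``x[axis] = cut``.

    Returns the two closed sub-polytopes as hulls of {vertices on each side}
    ∪ {edge–plane intersection points}; for a convex body this reconstruction
    is exact up to round-off.
    """
    v = mesh.vertices
    edges = set()
    for tri in mesh.faces:
        for i in range(3):
            e = (int(tri[i]), int(tri[(i + 1) % 3]))
            edges.add((min(e), max(e)))
    crossings = []
    for i, j in edges:
        ci, cj = v[i, axis] - cut, v[j, axis] - cut
        if ci * cj < 0:
            t = ci / (ci - cj)
            crossings.append(v[i] + t * (v[j] - v[i]))
    crossings = np.asarray(crossings).reshape(-1, 3)
    below = v[v[:, axis] <= cut]
    above = v[v[:, axis] >= cut]
    lower = convex_hull(PointCloud(np.vstack([below, crossings])))
    upper = convex_hull(PointCloud(np.vstack([above, crossings])))
    return lower, upper


@pytest.fixture
def mc_props():
    return mc_mass_properties


@pytest.fixture
def clip_mesh():
    return clip_convex_mesh
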