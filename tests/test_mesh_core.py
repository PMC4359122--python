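"""Geometry kernel: hulls, polyhedral integration, transforms, validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hullbsp import (
    DegenerateGeometryError,
    EmptyInputError,
    FrameMismatchError,
    InertialProperties,
    InvalidTransformError,
    MeshValidationError,
    PointCloud,
    RigidTransform,
    TriangleMesh,
    combine_properties,
    convex_hull,
    mass_properties,
    transform_properties,
    validate_mesh,
)

RHO = 1000.0


# ---------------------------------------------------------------------------
# convex_hull
# ---------------------------------------------------------------------------

class TestConvexHull:
    def test_unit_cube_identity(self, unit_cube_cloud):
        mesh = convex_hull(unit_cube_cloud)
        assert len(mesh.vertices) == 8
        assert len(mesh.faces) == 12
        rep = validate_mesh(mesh)
        assert rep.ok
        assert rep.signed_volume == pytest.approx(1.0, rel=1e-12)

    def test_interior_point_ignored(self, unit_cube_cloud):
        pts = np.vstack([unit_cube_cloud.points, [[0.5, 0.5, 0.5]]])
        mesh = convex_hull(PointCloud(pts))
        assert len(mesh.vertices) == 8
        assert validate_mesh(mesh).signed_volume == pytest.approx(1.0, rel=1e-12)
        # the interior point is absent from the hull vertices
        assert not any(np.allclose(v, [0.5, 0.5, 0.5]) for v in mesh.vertices)

    def test_ball_sample_volume_below_analytic_and_growing(self):
        """Hull of points inside the unit ball underestimates 4π/3 and grows with n."""
        rng = np.random.default_rng(42)
        ball = 4.0 / 3.0 * math.pi
        vols = []
        for n in (500, 5000):
            dirs = rng.normal(size=(n, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            pts = dirs * rng.uniform(0, 1, (n, 1)) ** (1 / 3)
            vols.append(validate_mesh(convex_hull(PointCloud(pts))).signed_volume)
        assert vols[0] < vols[1] < ball

    def test_ball_hull_matches_containment_oracle(self):
        """Hull volume of in-ball samples agrees with a Monte-Carlo containment
        estimate of the same hull (independent volume route)."""
        rng = np.random.default_rng(7)
        dirs = rng.normal(size=(500, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = dirs * rng.uniform(0, 1, (500, 1)) ** (1 / 3)
        mesh = convex_hull(PointCloud(pts))
        vol = validate_mesh(mesh).signed_volume
        # containment MC in the [-1,1]^3 box
        sample = rng.uniform(-1, 1, size=(1_000_000, 3))
        v = mesh.vertices
        a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
        n = np.cross(b - a, c - a)
        inside = np.all(sample @ n.T <= np.einsum("ij,ij->i", n, a) + 1e-12, axis=1)
        mc_vol = 8.0 * inside.mean()
        assert vol == pytest.approx(mc_vol, rel=0.01)

    def test_hull_contains_all_inputs(self, make_polytope):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(200, 3))
        mesh = convex_hull(PointCloud(pts))
        v = mesh.vertices
        a = v[mesh.faces[:, 0]]
        n = np.cross(v[mesh.faces[:, 1]] - a, v[mesh.faces[:, 2]] - a)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        d = pts @ n.T - np.einsum("ij,ij->i", n, a)
        assert d.max() <= 1e-9

    @pytest.mark.parametrize(
        "points",
        [
            np.zeros((0, 3)),
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]]),                    # < 4
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 3, 0]]),  # coplanar
            np.array([[float(k), 2.0 * k, 3.0 * k] for k in range(10)]),     # collinear
        ],
        ids=["empty", "three-points", "coplanar", "collinear"],
    )
    def test_degenerate_input_raises(self, points):
        with pytest.raises(DegenerateGeometryError):
            convex_hull(PointCloud(points))

    def test_hull_monotone_under_point_addition(self):
        """A ⊆ B implies hull volume(A) ≤ hull volume(B)."""
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(100, 3))
        prev = 0.0
        for n in (10, 30, 60, 100):
            vol = validate_mesh(convex_hull(PointCloud(pts[:n]))).signed_volume
            assert vol >= prev - 1e-12
            prev = vol


# ---------------------------------------------------------------------------
# mass_properties
# ---------------------------------------------------------------------------

class TestMassProperties:
    def test_unit_cube_closed_form(self, unit_cube_mesh):
        p = mass_properties(unit_cube_mesh, RHO)
        assert p.volume == pytest.approx(1.0, rel=1e-12)
        assert p.mass == pytest.approx(1000.0, rel=1e-12)
        assert p.com == pytest.approx([0.5, 0.5, 0.5], abs=1e-12)
        expected = 1000.0 / 6.0  # m L² / 6
        assert np.diag(p.inertia_com) == pytest.approx([expected] * 3, rel=1e-9)
        off = p.inertia_com - np.diag(np.diag(p.inertia_com))
        assert np.abs(off).max() < 1e-9 * expected

    def test_tetrahedron_volume_and_centroid(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        p = mass_properties(convex_hull(PointCloud(verts)), RHO)
        assert p.volume == pytest.approx(1.0 / 6.0, rel=1e-12)
        assert p.com == pytest.approx([0.25, 0.25, 0.25], abs=1e-12)

    def test_matches_monte_carlo_oracle(self, make_polytope, mc_props):
        """Polyhedral integrals vs rejection-sampling MC on random hulls."""
        for seed in (1, 2, 3):
            mesh = make_polytope(seed, n=40)
            p = mass_properties(mesh, RHO)
            vol, com, inertia, n_in = mc_props(mesh, RHO, 400_000, seed=seed + 100)
            radius = np.linalg.norm(
                mesh.vertices - mesh.vertices.mean(axis=0), axis=1
            ).max()
            assert p.volume == pytest.approx(vol, rel=0.01)
            assert np.linalg.norm(p.com - com) < 0.01 * radius
            assert np.abs(p.inertia_com - inertia).max() < 0.02 * np.abs(inertia).max()

    def test_origin_invariance(self, make_polytope):
        mesh = make_polytope(5)
        p0 = mass_properties(mesh, RHO)
        offset = np.array([123.4, -67.8, 901.2])
        p1 = mass_properties(TriangleMesh(mesh.vertices + offset, mesh.faces), RHO)
        assert p1.volume == pytest.approx(p0.volume, rel=1e-9)
        assert p1.com - offset == pytest.approx(p0.com, abs=1e-9 * np.abs(offset).max())
        assert p1.inertia_com == pytest.approx(p0.inertia_com, rel=1e-9)

    def test_rotation_equivariance(self, make_polytope):
        """mass_properties(rotate(mesh)) == transform_properties(mass_properties)."""
        mesh = make_polytope(6)
        p0 = mass_properties(mesh, RHO)
        xf = RigidTransform.from_rotation_about([1, 2, 3], 0.77, origin=[0.5, 0, -1])
        rotated = TriangleMesh(xf.apply(mesh.vertices), mesh.faces)
        p1 = mass_properties(rotated, RHO)
        p0x = transform_properties(p0, xf)
        assert p1.volume == pytest.approx(p0x.volume, rel=1e-9)
        assert p1.com == pytest.approx(p0x.com, abs=1e-9)
        assert p1.inertia_com == pytest.approx(p0x.inertia_com, rel=1e-9)

    def test_inertia_realisable_on_random_hulls(self, make_polytope):
        for seed in range(8):
            p = mass_properties(make_polytope(seed, scale=0.5 + seed * 0.3), RHO)
            assert p.is_realisable()

    def test_rejects_bad_meshes(self, unit_cube_mesh):
        holey = TriangleMesh(unit_cube_mesh.vertices, unit_cube_mesh.faces[:-1])
        with pytest.raises(MeshValidationError):
            mass_properties(holey, RHO)
        flipped_faces = unit_cube_mesh.faces.copy()
        flipped_faces[0] = flipped_faces[0][[0, 2, 1]]
        with pytest.raises(MeshValidationError):
            mass_properties(TriangleMesh(unit_cube_mesh.vertices, flipped_faces), RHO)
        inside_out = unit_cube_mesh.faces[:, [0, 2, 1]]
        with pytest.raises(MeshValidationError):
            mass_properties(TriangleMesh(unit_cube_mesh.vertices, inside_out), RHO)

    def test_rejects_nonpositive_density(self, unit_cube_mesh):
        with pytest.raises(ValueError):
            mass_properties(unit_cube_mesh, 0.0)


# ---------------------------------------------------------------------------
# transform_properties
# ---------------------------------------------------------------------------

class TestTransformProperties:
    def test_identity_is_noop(self, unit_cube_mesh):
        p = mass_properties(unit_cube_mesh, RHO)
        q = transform_properties(p, RigidTransform.identity())
        assert np.array_equal(q.com, p.com)
        assert q.inertia_com == pytest.approx(p.inertia_com, rel=1e-15)
        assert q.mass == p.mass and q.volume == p.volume

    def test_pure_translation_moves_com_only(self, unit_cube_mesh):
        p = mass_properties(unit_cube_mesh, RHO)
        xf = RigidTransform(np.eye(3), [0.0, 0.0, 5.0])
        q = transform_properties(p, xf)
        assert q.com == pytest.approx(p.com + [0, 0, 5], abs=1e-15)
        assert np.array_equal(q.inertia_com, p.inertia_com)

    def test_quarter_turn_permutes_moments(self):
        p = InertialProperties(1.0, 1.0, np.zeros(3), np.diag([1.0, 2.0, 3.0]))
        xf = RigidTransform.from_rotation_about([0, 0, 1], math.pi / 2)
        q = transform_properties(p, xf)
        assert q.inertia_com == pytest.approx(np.diag([2.0, 1.0, 3.0]), abs=1e-12)

    def test_invalid_rotation_rejected(self):
        with pytest.raises(InvalidTransformError):
            RigidTransform(np.diag([1.0, 1.0, 2.0]), np.zeros(3))
        with pytest.raises(InvalidTransformError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # reflection

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_invariance_of_inertia(self, tx, ty, tz):
        p = InertialProperties(1.0, 2.0, np.array([0.1, 0.2, 0.3]),
                               np.diag([1.0, 2.0, 2.5]))
        q = transform_properties(p, RigidTransform(np.eye(3), [tx, ty, tz]))
        assert np.array_equal(q.inertia_com, p.inertia_com)


# ---------------------------------------------------------------------------
# combine_properties
# ---------------------------------------------------------------------------

class TestCombineProperties:
    def test_single_part_identity(self, unit_cube_mesh):
        p = mass_properties(unit_cube_mesh, RHO)
        q = combine_properties([p])
        assert q.mass == pytest.approx(p.mass, rel=1e-15)
        assert q.com == pytest.approx(p.com, abs=1e-15)
        assert q.inertia_com == pytest.approx(p.inertia_com, rel=1e-12)

    def test_two_separated_cubes_closed_form(self):
        """Two unit cubes 2 m apart along x: parallel-axis closed form."""
        cube = lambda ox: InertialProperties(
            1.0, 1000.0, np.array([ox, 0.5, 0.5]), np.eye(3) * 1000.0 / 6.0
        )
        q = combine_properties([cube(0.5), cube(2.5)])
        assert q.mass == pytest.approx(2000.0)
        assert q.com == pytest.approx([1.5, 0.5, 0.5])
        assert q.inertia_com[0, 0] == pytest.approx(2000.0 / 6.0, rel=1e-12)
        # Iyy = Izz = 2 (mL²/6 + m d²) with d = 1 m
        expected = 2 * (1000.0 / 6.0 + 1000.0 * 1.0)
        assert q.inertia_com[1, 1] == pytest.approx(expected, rel=1e-12)
        assert q.inertia_com[2, 2] == pytest.approx(expected, rel=1e-12)

    def test_whole_equals_recombined_parts(self, make_polytope, clip_mesh):
        """Plane-split + parallel-axis recombination reproduces the whole body."""
        mesh = make_polytope(9, n=50)
        whole = mass_properties(mesh, RHO)
        lower, upper = clip_mesh(mesh, axis=2, cut=float(np.median(mesh.vertices[:, 2])))
        combined = combine_properties([
            mass_properties(lower, RHO), mass_properties(upper, RHO)
        ])
        assert combined.volume == pytest.approx(whole.volume, rel=1e-6)
        assert combined.mass == pytest.approx(whole.mass, rel=1e-6)
        assert np.linalg.norm(combined.com - whole.com) < 1e-6
        assert combined.inertia_com == pytest.approx(whole.inertia_com, rel=1e-6)

    def test_empty_and_mixed_frames_rejected(self):
        with pytest.raises(EmptyInputError):
            combine_properties([])
        a = InertialProperties(1.0, 1.0, np.zeros(3), np.eye(3), frame="world")
        b = InertialProperties(1.0, 1.0, np.zeros(3), np.eye(3), frame="segment")
        with pytest.raises(FrameMismatchError):
            combine_properties([a, b])


# ---------------------------------------------------------------------------
# validate_mesh
# ---------------------------------------------------------------------------

class TestValidateMesh:
    def test_cube_passes(self, unit_cube_mesh):
        rep = validate_mesh(unit_cube_mesh)
        assert rep.watertight and rep.consistent_orientation
        assert rep.signed_volume == pytest.approx(1.0, rel=1e-12)
        assert rep.boundary_edge_count == 0

    def test_missing_face_detected(self, unit_cube_mesh):
        rep = validate_mesh(TriangleMesh(unit_cube_mesh.vertices,
                                         unit_cube_mesh.faces[:-1]))
        assert not rep.watertight
        assert rep.boundary_edge_count == 3

    def test_flipped_face_detected(self, unit_cube_mesh):
        faces = unit_cube_mesh.faces.copy()
        faces[4] = faces[4][[0, 2, 1]]
        rep = validate_mesh(TriangleMesh(unit_cube_mesh.vertices, faces))
        assert rep.watertight
        assert not rep.consistent_orientation

    def test_never_raises_on_empty(self):
        rep = validate_mesh(TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)))
        assert not rep.watertight
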