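"""Geometric primitives: head frame, planes, reflection, ICP, distances."""

import numpy as np
import pytest
import trimesh
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from facesym import (
    GeometryError,
    LandmarkSet3D,
    MissingLandmarkError,
    Plane,
    RigidTransform,
    fit_head_frame,
    icp_best_fit,
    midsagittal_plane,
    mirror_mesh,
    signed_distance_to_surface,
)
from facesym.geometry import closest_points_on_surface


def random_rigid(seed: int, max_deg: float = 40.0, max_mm: float = 30.0) -> RigidTransform:
    rng = np.random.default_rng(seed)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(rng.uniform(0, max_deg)) * axis).as_matrix()
    return RigidTransform(R, rng.uniform(-max_mm, max_mm, 3))


# ---------------------------------------------------------------------------
# Head frame
# ---------------------------------------------------------------------------


class TestHeadFrame:
    def test_axis_aligned_head_gives_coordinate_axes(self, axis_aligned_landmarks):
        frame = fit_head_frame(axis_aligned_landmarks)
        np.testing.assert_allclose(frame.axis_transverse, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.axis_anterior, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(frame.axis_vertical, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(frame.origin, [0, 0, 0], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rotation_covariance(self, axis_aligned_landmarks, seed):
        """Rigidly moving the landmarks rotates the frame axes identically."""
        T = random_rigid(seed)
        moved = axis_aligned_landmarks.transformed(T)
        f0 = fit_head_frame(axis_aligned_landmarks)
        f1 = fit_head_frame(moved)
        for ax in ("axis_transverse", "axis_vertical", "axis_anterior"):
            np.testing.assert_allclose(
                getattr(f1, ax), T.rotation @ getattr(f0, ax), atol=1e-6
            )
        np.testing.assert_allclose(f1.origin, T.apply(f0.origin[None])[0], atol=1e-6)

    def test_coincident_tragia_is_geometry_error(self, axis_aligned_landmarks):
        axis_aligned_landmarks["tragion_l"] = axis_aligned_landmarks["tragion_r"]
        with pytest.raises(GeometryError):
            fit_head_frame(axis_aligned_landmarks)

    def test_collinear_landmarks_is_geometry_error(self, axis_aligned_landmarks):
        axis_aligned_landmarks["exocanthion_r"] = (-30.0, 0.0, 0.0)
        axis_aligned_landmarks["exocanthion_l"] = (30.0, 0.0, 0.0)
        with pytest.raises(GeometryError):
            fit_head_frame(axis_aligned_landmarks)

    def test_missing_landmark_is_named(self):
        with pytest.raises(MissingLandmarkError, match="tragion_l"):
            fit_head_frame(LandmarkSet3D.from_mapping({"tragion_r": (0, 0, 0)}))


# ---------------------------------------------------------------------------
# Midsagittal plane
# ---------------------------------------------------------------------------


class TestMidsagittalPlane:
    def test_symmetric_landmarks_give_x_equals_zero(self, axis_aligned_landmarks):
        frame = fit_head_frame(axis_aligned_landmarks)
        plane = midsagittal_plane(axis_aligned_landmarks, frame)
        np.testing.assert_allclose(plane.normal, [1, 0, 0], atol=1e-12)
        assert abs(plane.signed_distance([[0.0, 50.0, 50.0]])[0]) < 1e-12

    def test_offset_landmarks_give_parallel_plane(self, axis_aligned_landmarks):
        axis_aligned_landmarks["sellion"] = (2.0, 80.0, 90.0)
        axis_aligned_landmarks["subnasale"] = (2.0, 95.0, 40.0)
        frame = fit_head_frame(axis_aligned_landmarks)
        plane = midsagittal_plane(axis_aligned_landmarks, frame)
        np.testing.assert_allclose(plane.normal, [1, 0, 0], atol=1e-12)
        assert abs(plane.signed_distance([[2.0, 0.0, 0.0]])[0]) < 1e-12

    @pytest.mark.parametrize("seed", [3, 4])
    def test_construction_is_covariant(self, axis_aligned_landmarks, seed):
        """Transform-then-construct equals construct-then-transform."""
        T = random_rigid(seed)
        frame = fit_head_frame(axis_aligned_landmarks)
        p_then_t = midsagittal_plane(axis_aligned_landmarks, frame).transformed(T)
        moved = axis_aligned_landmarks.transformed(T)
        t_then_p = midsagittal_plane(moved, fit_head_frame(moved))
        np.testing.assert_allclose(t_then_p.normal, p_then_t.normal, atol=1e-6)
        assert abs(t_then_p.signed_distance(p_then_t.point[None])[0]) < 1e-6

    def test_coincident_se_sn_is_geometry_error(self, axis_aligned_landmarks):
        axis_aligned_landmarks["subnasale"] = axis_aligned_landmarks["sellion"]
        frame = fit_head_frame(axis_aligned_landmarks)
        with pytest.raises(GeometryError):
            midsagittal_plane(axis_aligned_landmarks, frame)


# ---------------------------------------------------------------------------
# Reflection
# ---------------------------------------------------------------------------


class TestMirrorMesh:
    def _mesh(self):
        return trimesh.creation.icosphere(subdivisions=2)

    def test_axis_aligned_reflection_of_vertex(self):
        plane = Plane([0, 0, 0], [1, 0, 0])
        assert np.allclose(plane.reflect([[3.0, 1.0, 2.0]]), [[-3.0, 1.0, 2.0]])

    @given(
        nx=st.floats(-1, 1), ny=st.floats(-1, 1), nz=st.floats(0.1, 1),
        px=st.floats(-5, 5),
    )
    def test_reflection_is_involution_and_isometry(self, nx, ny, nz, px):
        n = np.array([nx, ny, nz])
        n /= np.linalg.norm(n)
        plane = Plane([px, 0.0, 0.0], n)
        mesh = self._mesh()
        once = mirror_mesh(mesh, plane)
        twice = mirror_mesh(once, plane)
        np.testing.assert_allclose(twice.vertices, mesh.vertices, atol=1e-9)
        np.testing.assert_array_equal(twice.faces, mesh.faces)
        assert abs(once.area - mesh.area) <= 1e-9 * mesh.area

    def test_winding_flip_preserves_outward_orientation(self):
        mesh = self._mesh()
        mirrored = mirror_mesh(mesh, Plane([0, 0, 0], [1, 0, 0]))
        # outward normals of a reflected sphere still point away from centre
        outward = np.einsum(
            "ij,ij->i", mirrored.face_normals, mirrored.triangles_center
        )
        assert np.all(outward > 0)


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def face_mesh():
    from facesym import FaceSpec, generate_face

    return generate_face(FaceSpec(target_faces=4000)).mesh


class TestICP:
    def test_identical_meshes_give_identity(self, face_mesh):
        res = icp_best_fit(face_mesh, face_mesh)
        assert res.converged
        assert res.rms < 1e-9
        assert res.transform.rotation_angle_deg() < 1e-9
        assert np.linalg.norm(res.transform.translation) < 1e-9

    def test_known_motion_recovered(self, face_mesh):
        R = Rotation.from_euler("z", 5, degrees=True).as_matrix()
        gt = RigidTransform(R, np.array([2.0, 0.0, 0.0]))
        target = trimesh.Trimesh(gt.apply(face_mesh.vertices), face_mesh.faces,
                                 process=False)
        res = icp_best_fit(face_mesh, target, tol=1e-6, trim_fraction=0.0,
                           max_iter=1000)
        dev = res.transform.compose(gt.inverse())
        assert dev.rotation_angle_deg() < 1e-3
        assert np.linalg.norm(res.transform.translation - gt.translation) < 1e-3

    def test_subsampled_source_gives_same_transform(self, face_mesh):
        R = Rotation.from_euler("z", 5, degrees=True).as_matrix()
        gt = RigidTransform(R, np.array([2.0, 0.0, 0.0]))
        target = trimesh.Trimesh(gt.apply(face_mesh.vertices), face_mesh.faces,
                                 process=False)
        sub = trimesh.Trimesh(face_mesh.vertices[::4], [[0, 1, 2]], process=False)
        res = icp_best_fit(sub, target)
        dev = res.transform.compose(gt.inverse())
        assert dev.rotation_angle_deg() < 1e-2
        assert np.linalg.norm(res.transform.translation - gt.translation) < 1e-2

    def test_nonconvergence_sets_flag_not_exception(self, face_mesh):
        R = Rotation.from_euler("y", 8, degrees=True).as_matrix()
        target = trimesh.Trimesh(
            (face_mesh.vertices @ R.T) + [5, 0, 0], face_mesh.faces, process=False
        )
        res = icp_best_fit(face_mesh, target, max_iter=1)
        assert res.converged is False
        assert np.isfinite(res.rms)


# ---------------------------------------------------------------------------
# Signed distance
# ---------------------------------------------------------------------------


class TestSignedDistance:
    def test_point_on_surface_is_zero(self, face_mesh):
        pts = face_mesh.triangles_center[:50]
        d = signed_distance_to_surface(pts, face_mesh)
        assert np.abs(d).max() < 1e-9

    def test_sphere_distances_match_analytic(self):
        sphere = trimesh.creation.icosphere(subdivisions=4)  # fine tessellation
        d_out = signed_distance_to_surface([[2.0, 0, 0]], sphere)[0]
        d_in = signed_distance_to_surface([[0.5, 0, 0]], sphere)[0]
        assert d_out == pytest.approx(1.0, abs=5e-3)
        assert d_in == pytest.approx(-0.5, abs=5e-3)

    def test_empty_point_list(self, face_mesh):
        assert signed_distance_to_surface(np.zeros((0, 3)), face_mesh).shape == (0,)

    def test_matches_exhaustive_scan(self, rng):
        """Candidate-pruned closest point equals the all-triangles scan."""
        mesh = trimesh.creation.icosphere(subdivisions=3)  # 1280 faces
        pts = rng.uniform(-1.5, 1.5, (200, 3))
        _, dist, _ = closest_points_on_surface(mesh, pts)
        # independent exhaustive scan
        tri = mesh.triangles
        brute = np.empty(len(pts))
        for i, p in enumerate(pts):
            cp = trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1)))
            brute[i] = np.sqrt(((cp - p) ** 2).sum(axis=1).min())
        np.testing.assert_allclose(dist, brute, atol=1e-12)
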