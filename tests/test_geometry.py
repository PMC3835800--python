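"""Camera model, epipolar geometry, triangulation and rigid-fit tests."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gridstereo.errors import (
    DegenerateGeometryError,
    DegenerateRigError,
    DistortionInversionError,
    NonProjectablePointError,
    NonTriangulablePairError,
)
from gridstereo.geometry import (
    CameraModel,
    RigidTransform,
    StereoRig,
    estimate_rigid,
    fundamental_matrix,
    project,
    triangulate,
    undistort,
    undistorted_pixels,
)


def _random_camera(rng, distorted=True):
    k1, k2, p1, p2 = (rng.uniform(-0.1, 0.1, 4) * [1, 0.1, 0.05, 0.05]) if distorted else (
        0.0, 0.0, 0.0, 0.0)
    return CameraModel(
        fx=rng.uniform(400, 900), fy=rng.uniform(400, 900),
        cx=rng.uniform(280, 360), cy=rng.uniform(200, 280),
        width=640, height=480, k1=k1, k2=k2, p1=p1, p2=p2,
    )


def _random_rig(rng, distorted=True):
    R = Rotation.from_rotvec(rng.uniform(-0.05, 0.05, 3)).as_matrix()
    t = rng.uniform(-1, 1, 3)
    t[0] += 5.0  # guarantee a baseline
    return StereoRig(left=_random_camera(rng, distorted),
                     right=_random_camera(rng, distorted), rotation=R, translation=t)


class TestProjection:
    def test_optical_axis_maps_to_principal_point(self):
        cam = CameraModel(fx=1, fy=1, cx=0, cy=0, width=10, height=10)
        px = project(cam, RigidTransform.identity(), np.array([0.0, 0.0, 1.0]))
        assert np.allclose(px, [0.0, 0.0])

    def test_pinhole_hand_evaluation(self):
        # u = fx * X/Z + cx = 100 * 0.1 + 50 = 60
        cam = CameraModel(fx=100, fy=100, cx=50, cy=50, width=200, height=200)
        px = project(cam, RigidTransform.identity(), np.array([0.1, 0.0, 1.0]))
        assert np.allclose(px, [60.0, 50.0])

    def test_zero_depth_raises(self):
        cam = CameraModel(fx=100, fy=100, cx=50, cy=50, width=200, height=200)
        with pytest.raises(NonProjectablePointError):
            project(cam, RigidTransform.identity(), np.array([0.1, 0.0, 0.0]))

    def test_zero_distortion_equals_ideal_pinhole(self, rng):
        cam = _random_camera(rng, distorted=False)
        pts = rng.uniform([-5, -5, 20], [5, 5, 40], size=(50, 3))
        px = project(cam, RigidTransform.identity(), pts)
        ideal = cam.pixels_from_normalized(pts[:, :2] / pts[:, 2:3])
        assert np.allclose(px, ideal, atol=1e-12)


class TestUndistortion:
    def test_principal_point_maps_to_origin(self):
        cam = CameraModel(fx=700, fy=700, cx=320, cy=240, width=640, height=480)
        assert np.allclose(undistort(cam, np.array([320.0, 240.0])), [0.0, 0.0])

    def test_round_trip_over_distortion_settings(self, rng):
        # distort(undistort(p)) = p to <1e-8 px for random in-bounds pixels
        for _ in range(10):
            cam = _random_camera(rng)
            px = rng.uniform([50, 50], [590, 430], size=(200, 2))
            n = undistort(cam, px)
            back = cam.pixels_from_normalized(cam.distort_normalized(n))
            assert np.max(np.abs(back - px)) < 1e-8

    def test_divergent_inversion_raises(self):
        cam = CameraModel(fx=300, fy=300, cx=320, cy=240, width=640, height=480, k1=-3.0)
        with pytest.raises(DistortionInversionError):
            undistort(cam, np.array([639.0, 479.0]))


class TestFundamentalMatrix:
    def test_rectified_rig_gives_horizontal_epipolar_lines(self):
        cam = CameraModel(fx=700, fy=700, cx=320, cy=240, width=640, height=480)
        rig = StereoRig(left=cam, right=cam, rotation=np.eye(3),
                        translation=np.array([5.0, 0.0, 0.0]))
        F = fundamental_matrix(rig)
        line = F @ np.array([300.0, 200.0, 1.0])
        # horizontal line: zero coefficient on x
        assert abs(line[0]) < 1e-12 * np.linalg.norm(line)

    def test_projected_pairs_satisfy_epipolar_constraint(self, rng):
        # forward-projection oracle: x_r^T F x_l = 0 for true correspondences
        for _ in range(5):
            rig = _random_rig(rng)
            F = fundamental_matrix(rig)
            pts = rng.uniform([-5, -5, 25], [5, 5, 40], size=(100, 3))
            pl = undistorted_pixels(rig.left, project(rig.left, RigidTransform.identity(), pts))
            pr = undistorted_pixels(rig.right, project(rig.right, rig.relative, pts))
            hl = np.concatenate([pl, np.ones((len(pl), 1))], axis=1)
            hr = np.concatenate([pr, np.ones((len(pr), 1))], axis=1)
            residual = np.abs(np.einsum("ij,jk,ik->i", hr, F, hl))
            assert residual.max() < 1e-9

    def test_rank_two_and_unit_norm(self, rng):
        F = fundamental_matrix(_random_rig(rng))
        assert np.isclose(np.linalg.norm(F), 1.0)
        assert np.linalg.matrix_rank(F, tol=1e-10) == 2

    def test_zero_baseline_raises(self):
        cam = CameraModel(fx=700, fy=700, cx=320, cy=240, width=640, height=480)
        with pytest.raises(DegenerateRigError):
            fundamental_matrix(StereoRig(left=cam, right=cam, rotation=np.eye(3),
                                         translation=np.zeros(3)))


class TestTriangulation:
    def test_exact_projections_recover_point(self, rng):
        cam = CameraModel(fx=700, fy=700, cx=320, cy=240, width=640, height=480)
        rig = StereoRig(left=cam, right=cam, rotation=np.eye(3),
                        translation=np.array([-4.0, 0.0, 0.0]))
        p = np.array([10.0, -5.0, 80.0])
        pl = project(rig.left, RigidTransform.identity(), p)
        pr = project(rig.right, rig.relative, p)
        rec, gap = triangulate(rig, pl, pr)
        assert np.linalg.norm(rec - p) < 1e-6
        assert gap < 1e-9

    def test_round_trip_over_random_rigs(self, rng):
        # 1000 random points across 10 random rigs, recovered to < 1e-6 mm
        for _ in range(10):
            rig = _random_rig(rng)
            pts = rng.uniform([-5, -5, 25], [5, 5, 45], size=(100, 3))
            pl = project(rig.left, RigidTransform.identity(), pts)
            pr = project(rig.right, rig.relative, pts)
            rec, gap = triangulate(rig, pl, pr)
            assert np.max(np.linalg.norm(rec - pts, axis=1)) < 1e-6
            assert np.max(gap) < 1e-9

    def test_error_scales_inversely_with_baseline(self, rng):
        cam = CameraModel(fx=700, fy=700, cx=320, cy=240, width=640, height=480)
        p = np.array([2.0, 1.0, 30.0])
        errors = []
        for baseline in (2.0, 8.0):
            rig = StereoRig(left=cam, right=cam, rotation=np.eye(3),
                            translation=np.array([-baseline, 0.0, 0.0]))
            pl = project(rig.left, RigidTransform.identity(), p) + [1.0, 0.0]
            pr = project(rig.right, rig.relative, p)
            rec, gap = triangulate(rig, pl, pr)
            assert gap > 0
            errors.append(np.linalg.norm(rec - p))
        assert errors[0] > errors[1]  # smaller baseline -> larger error

    def test_parallel_rays_raise(self):
        cam = CameraModel(fx=700, fy=700, cx=320, cy=240, width=640, height=480)
        rig = StereoRig(left=cam, right=cam, rotation=np.eye(3),
                        translation=np.array([-4.0, 0.0, 0.0]))
        with pytest.raises(NonTriangulablePairError):
            # identical pixels in a fronto-parallel rig: rays are parallel
            triangulate(rig, np.array([320.0, 240.0]), np.array([320.0, 240.0]))


class TestEstimateRigid:
    def test_identity_for_identical_clouds(self, rng):
        pts = rng.normal(size=(20, 3))
        T = estimate_rigid(pts, pts)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0, atol=1e-12)

    def test_recovers_random_transforms_exactly(self, rng):
        # 1000 random transforms, exact recovery and no reflections
        for _ in range(1000):
            pts = rng.normal(size=(10, 3))
            R0 = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            t0 = rng.uniform(-50, 50, 3)
            T = estimate_rigid(pts, pts @ R0.T + t0)
            assert np.linalg.det(T.rotation) > 0
            assert np.max(np.abs(T.rotation - R0)) < 1e-9
            assert np.max(np.abs(T.translation - t0)) < 1e-9

    def test_weights_downweight_outlier(self, rng):
        pts = rng.normal(size=(12, 3))
        R0 = Rotation.from_rotvec([0.1, -0.2, 0.05]).as_matrix()
        target = pts @ R0.T + np.array([1.0, 2.0, 3.0])
        target[0] += 100.0  # gross outlier
        w = np.ones(12)
        w[0] = 0.0
        T = estimate_rigid(pts, target, weights=w)
        assert np.max(np.abs(T.rotation - R0)) < 1e-9

    def test_collinear_points_raise(self):
        pts = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid(pts, pts)

    def test_too_few_points_raise(self):
        pts = np.eye(3)[:2]
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid(pts, pts)


class TestRigidTransform:
    def test_compose_inverse_is_identity(self, rng):
        for _ in range(20):
            T = RigidTransform(
                Rotation.random(random_state=int(rng.integers(2**31))).as_matrix(),
                rng.uniform(-10, 10, 3),
            )
            I = T.compose(T.inverse())
            assert np.allclose(I.rotation, np.eye(3), atol=1e-9)
            assert np.allclose(I.translation, 0, atol=1e-9)

    def test_compose_order(self, rng):
        A = RigidTransform.from_axis_angle([0, 0, 0.3], [1.0, 0, 0])
        B = RigidTransform.from_axis_angle([0.2, 0, 0], [0, 2.0, 0])
        p = rng.normal(size=3)
        assert np.allclose(A.compose(B).apply(p), A.apply(B.apply(p)))
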