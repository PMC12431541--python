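"""Camera model, rays, triangulation and DLT resection."""

import json

import numpy as np
import pytest

from rgbmocap import geometry as g


def canonical_camera(scale=1.0):
    return g.CameraModel("c", scale * np.hstack([np.eye(3), np.zeros((3, 1))]), 1920, 1080)


def random_camera(rng):
    while True:
        P = rng.standard_normal((3, 4))
        if abs(np.linalg.det(P[:, :3])) > 0.1:
            return g.CameraModel("r", P, 1920, 1080)


class TestProject:
    def test_canonical_camera_center_pixel(self):
        assert g.project(canonical_camera(), (0, 0, 1000)) == pytest.approx((0.0, 0.0))

    def test_scaling_P_does_not_change_projection(self):
        p1 = g.project(canonical_camera(), (10, 20, 1000))
        p2 = g.project(canonical_camera(scale=7.0), (10, 20, 1000))
        assert p1 == pytest.approx(p2, abs=0)

    def test_point_behind_camera_is_flagged(self):
        with pytest.raises(g.BehindCameraError):
            g.project(canonical_camera(), (0, 0, -1000))

    def test_project_pixel_to_ray_roundtrip(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            cam = random_camera(rng)
            X = rng.uniform(-1000, 1000, 3)
            if g.projective_depth(cam, X) <= 0:
                X = 2 * cam.center - X
            ray = g.pixel_to_ray(cam, g.project(cam, X))
            assert g.point_ray_distance(X, ray, half_line=False) < 1e-9


class TestPixelToRay:
    def test_canonical_camera_principal_ray(self):
        ray = g.pixel_to_ray(canonical_camera(), (0, 0))
        assert ray.origin == pytest.approx((0, 0, 0))
        assert ray.direction == pytest.approx((0, 0, 1))

    def test_points_on_ray_reproject_to_pixel(self):
        rng = np.random.default_rng(1)
        cam = random_camera(rng)
        pix = np.array([123.4, -56.7])
        ray = g.pixel_to_ray(cam, pix)
        for t in rng.uniform(1.0, 1e4, 100):
            back = np.asarray(g.project(cam, ray.point_at(t), strict=False))
            assert np.abs(back - pix).max() < 1e-9 * max(1.0, np.abs(pix).max())

    def test_ray_origin_is_camera_center(self):
        rng = np.random.default_rng(2)
        cam = random_camera(rng)
        ray = g.pixel_to_ray(cam, (5, 5))
        # the camera centre is the null space of P: projection is undefined there
        assert np.linalg.norm(cam.P @ np.append(ray.origin, 1.0)) < 1e-9

    def test_singular_camera_rejected(self):
        P = np.zeros((3, 4))
        P[0, 0] = P[1, 1] = 1.0
        P[2, 3] = 1.0
        cam = g.CameraModel("s", P, 10, 10)
        with pytest.raises(g.InvalidCameraError):
            cam.validate()


class TestPointRayDistance:
    def test_point_on_ray_is_zero(self):
        ray = g.Ray(origin=(0, 0, 0), direction=(0, 0, 1))
        assert g.point_ray_distance((0, 0, 500), ray) == 0.0

    def test_unit_perpendicular_offset(self):
        ray = g.Ray(origin=(0, 0, 0), direction=(0, 0, 1))
        assert g.point_ray_distance((1, 0, 500), ray) == pytest.approx(1.0)

    def test_matches_cross_product_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            o, d, p = rng.standard_normal((3, 3))
            ray = g.Ray(origin=o, direction=d)
            expected = np.linalg.norm(np.cross(p - o, ray.direction))
            if (p - o) @ ray.direction >= 0:
                assert g.point_ray_distance(p, ray) == pytest.approx(expected, abs=1e-12)
            else:
                # behind the origin: half-line semantics measure to the origin
                assert g.point_ray_distance(p, ray) == pytest.approx(
                    np.linalg.norm(p - o), abs=1e-12
                )
                assert g.point_ray_distance(p, ray, half_line=False) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_behind_flag_via_foot_parameter(self):
        ray = g.Ray(origin=(0, 0, 0), direction=(0, 0, 1))
        assert g.ray_foot_parameter((0, 0, -5), ray) < 0
        assert g.point_ray_distance((0, 0, -5), ray) == pytest.approx(5.0)


class TestTriangulate:
    def test_noiseless_recovery(self, default_rig):
        X = np.array([900.0, 2100.0, 1100.0])
        obs = [(c, g.project(c, X)) for c in default_rig[:3]]
        res = g.triangulate(obs)
        assert np.linalg.norm(res.point - X) < 1e-6
        assert res.distances.max() < 1e-6

    def test_two_skew_rays_give_midpoint(self):
        r1 = g.Ray(origin=(-10, 0, 0), direction=(1, 0, 0))
        r2 = g.Ray(origin=(0, 1, -10), direction=(0, 0, 1))
        res = g.triangulate_rays([r1, r2])
        # common perpendicular joins (0,0,0) and (0,1,0): midpoint between them
        assert res.point == pytest.approx((0.0, 0.5, 0.0), abs=1e-9)
        assert res.distances == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_single_observation_rejected(self, default_rig):
        with pytest.raises(g.DegenerateGeometryError):
            g.triangulate([(default_rig[0], (0.0, 0.0))])

    def test_parallel_rays_rejected(self):
        r1 = g.Ray(origin=(0, 0, 0), direction=(0, 0, 1))
        r2 = g.Ray(origin=(5, 0, 0), direction=(0, 0, 1))
        with pytest.raises(g.DegenerateGeometryError):
            g.triangulate_rays([r1, r2])

    def test_shared_camera_center_rejected(self, default_rig):
        cam = default_rig[0]
        with pytest.raises(g.DegenerateGeometryError):
            g.triangulate([(cam, (0.0, 0.0)), (cam, (10.0, 10.0))])

    def test_rigid_invariance(self, default_rig):
        """Ray distances are unchanged when cameras and points move together."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        X = np.array([1100.0, 1900.0, 800.0])
        obs = [
            (c, np.asarray(g.project(c, X)) + rng.normal(0, 1, 2))
            for c in default_rig[:4]
        ]
        res = g.triangulate(obs)
        R = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        t = np.array([500.0, -200.0, 900.0])
        moved = [
            (g.CameraModel(c.id, c.P @ np.block([[R.T, (-R.T @ t)[:, None]], [np.zeros((1, 3)), 1.0]]), c.image_width, c.image_height), px)
            for c, px in obs
        ]
        res2 = g.triangulate(moved)
        assert res2.distances == pytest.approx(res.distances, abs=1e-9)
        assert R @ res.point + t == pytest.approx(res2.point, abs=1e-6)


class TestDltCalibrate:
    def test_recovers_camera_up_to_scale(self, default_rig):
        rng = np.random.default_rng(5)
        cam = default_rig[0]
        X = rng.uniform(0, 2000, (20, 3))
        pix = np.array([g.project(cam, x, strict=False) for x in X])
        est = g.dlt_calibrate(X, pix)
        Pn = cam.P / np.linalg.norm(cam.P)
        if np.sign(np.linalg.det(Pn[:, :3])) != np.sign(np.linalg.det(est.P[:, :3])):
            Pn = -Pn
        assert est.P == pytest.approx(Pn, abs=1e-9)

    def test_noisy_reprojection_rms_bounded(self, default_rig):
        rng = np.random.default_rng(6)
        cam = default_rig[1]
        X = rng.uniform(0, 2000, (60, 3))
        pix = np.array([g.project(cam, x, strict=False) for x in X])
        noisy = pix + rng.normal(0, 0.5, pix.shape)
        est = g.dlt_calibrate(X, noisy)
        re = np.array([g.project(est, x, strict=False) for x in X])
        rms = np.sqrt(np.mean(np.sum((re - noisy) ** 2, axis=1) / 2))
        assert rms <= 1.5 * 0.5

    def test_five_points_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(g.DegenerateGeometryError):
            g.dlt_calibrate(rng.uniform(0, 1, (5, 3)), rng.uniform(0, 1, (5, 2)))

    def test_coplanar_points_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1000, (10, 3))
        X[:, 2] = 100.0
        with pytest.raises(g.DegenerateGeometryError):
            g.dlt_calibrate(X, rng.uniform(0, 1000, (10, 2)))


class TestCameraIO:
    def test_bit_exact_roundtrip(self, tmp_path, default_rig):
        path = tmp_path / "cameras.json"
        g.save_cameras(path, default_rig)
        back = g.load_cameras(path)
        for a, b in zip(default_rig, back):
            assert a.id == b.id
            assert (a.P == b.P).all()  # bit exact, not approx
            assert (a.image_width, a.image_height) == (b.image_width, b.image_height)

    def test_file_is_plain_json_records(self, tmp_path, default_rig):
        path = tmp_path / "cameras.json"
        g.save_cameras(path, default_rig)
        records = json.loads(path.read_text())
        assert len(records) == len(default_rig)
        assert len(records[0]["P"]) == 12
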