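"""Unit and property tests for the pinhole models and the mapping chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermomap as tm
from thermomap import camera_geometry as cg
from thermomap.errors import (
    ConvergenceError,
    InsufficientDataError,
    InvalidDepthError,
    InvalidInputError,
    PrincipalPointWarning,
    ProjectionError,
)

INTR = cg.Intrinsics(1000.0, 1000.0, 1344.0, 760.0, 2688, 1520)


class TestDomainTypes:
    def test_invalid_focal_rejected(self):
        with pytest.raises(InvalidInputError):
            cg.Intrinsics(-1.0, 1000.0, 0.0, 0.0, 10, 10)

    def test_principal_point_outside_image_warns_not_fails(self):
        with pytest.warns(PrincipalPointWarning):
            intr = cg.Intrinsics(500.0, 500.0, 900.0, 10.0, 640, 480)
        assert intr.cx == 900.0

    def test_rotation_must_be_orthonormal(self):
        bad = np.eye(3)
        bad[0, 1] = 1e-6
        with pytest.raises(InvalidInputError):
            cg.RigExtrinsics(bad, np.zeros(3))

    def test_reflection_rejected(self):
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(InvalidInputError):
            cg.RigExtrinsics(refl, np.zeros(3))

    def test_homogeneous_matrix_round_trip(self):
        ext = tm.make_rig("realistic", seed=1).extrinsics
        again = cg.RigExtrinsics.from_matrix(ext.matrix)
        np.testing.assert_allclose(again.rotation, ext.rotation)
        np.testing.assert_allclose(again.translation, ext.translation)

    def test_board_inner_corner_grid(self):
        board = cg.CheckerboardSpec(15, 16, 25.0)
        assert (board.inner_cols, board.inner_rows) == (14, 15)
        assert board.n_corners == 210
        pts = board.corner_points_mm(board.corner_grid())
        assert pts.shape == (210, 3)
        assert pts[:, 2].max() == 0.0
        assert pts[:, 0].max() == 13 * 25.0

    def test_emissivity_bounds(self):
        rig = tm.make_rig("identity")
        with pytest.raises(InvalidInputError):
            cg.CameraRig(rig.rgb, rig.ir, rig.extrinsics, emissivity=0.0)


class TestNormalization:
    def test_principal_point_maps_to_origin(self):
        np.testing.assert_array_equal(
            cg.normalize_pixel((1344.0, 760.0), INTR), [0.0, 0.0]
        )

    def test_direct_substitution(self):
        np.testing.assert_allclose(
            cg.normalize_pixel((2344.0, 760.0), INTR), [1.0, 0.0]
        )

    def test_round_trip_with_projection(self, rng):
        pts = rng.uniform(0, [2688, 1520], size=(100, 2))
        back = cg.denormalize_point(cg.normalize_pixel(pts, INTR), INTR)
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            cg.normalize_pixel((np.nan, 0.0), INTR)


class TestDistortion:
    def test_zero_coefficients_identity(self, rng):
        n = rng.uniform(-0.5, 0.5, (50, 2))
        d = cg.DistortionCoeffs()
        np.testing.assert_array_equal(cg.distort_normalized(n, d), n)
        np.testing.assert_array_equal(cg.undistort_normalized(n, d), n)

    def test_radial_term(self):
        d = cg.DistortionCoeffs(k1=0.1)
        out = cg.distort_normalized((0.1, 0.0), d)
        np.testing.assert_allclose(out, [0.1 * (1 + 0.1 * 0.01), 0.0])

    def test_tangential_term(self):
        d = cg.DistortionCoeffs(p1=0.01)
        out = cg.distort_normalized((0.1, 0.1), d)
        assert out[0] == pytest.approx(0.1 + 2 * 0.01 * 0.01)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        k1=st.floats(-0.3, 0.3),
        k2=st.floats(-0.05, 0.05),
        p1=st.floats(-0.005, 0.005),
        p2=st.floats(-0.005, 0.005),
        x=st.floats(-0.5, 0.5),
        y=st.floats(-0.5, 0.5),
    )
    def test_undistort_inverts_distort(self, k1, k2, p1, p2, x, y):
        d = cg.DistortionCoeffs(k1, k2, p1, p2, 0.0)
        n = np.array([x, y])
        roundtrip = cg.undistort_normalized(cg.distort_normalized(n, d), d)
        np.testing.assert_allclose(roundtrip, n, atol=1e-8)

    def test_pathological_coefficients_raise(self):
        d = cg.DistortionCoeffs(k1=-10.0)
        with pytest.raises(ConvergenceError):
            cg.undistort_normalized((0.7, 0.7), d)


class TestBackprojectAndTransform:
    def test_optical_axis(self):
        np.testing.assert_array_equal(
            cg.backproject_at_depth((0.0, 0.0), 600.0), [0, 0, 600]
        )

    def test_direct_substitution(self):
        np.testing.assert_array_equal(
            cg.backproject_at_depth((1.0, 0.5), 600.0), [600, 300, 600]
        )

    @pytest.mark.parametrize("depth", [0.0, -5.0, np.nan])
    def test_bad_depth(self, depth):
        with pytest.raises(InvalidDepthError):
            cg.backproject_at_depth((0.0, 0.0), depth)

    def test_identity_transform(self):
        p = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(
            cg.transform_rgb_to_ir(p, cg.RigExtrinsics.identity()), p
        )

    def test_pure_translation(self):
        ext = cg.RigExtrinsics(np.eye(3), [30.0, 0.0, 0.0])
        np.testing.assert_array_equal(
            cg.transform_rgb_to_ir([0.0, 0.0, 600.0], ext), [30, 0, 600]
        )

    def test_rotation_about_z(self):
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        ext = cg.RigExtrinsics(Rz, np.zeros(3))
        np.testing.assert_allclose(
            cg.transform_rgb_to_ir([1.0, 0.0, 0.0], ext), [0, 1, 0], atol=1e-12
        )


class TestProjection:
    IR = cg.Intrinsics(500.0, 500.0, 192.0, 144.0, 384, 288)
    D0 = cg.DistortionCoeffs()

    def test_on_axis_hits_principal_point(self):
        u, v = cg.project_to_ir([0.0, 0.0, 600.0], self.IR, self.D0)
        assert (u, v) == (192.0, 144.0)

    def test_direct_substitution(self):
        u, _ = cg.project_to_ir([60.0, 0.0, 600.0], self.IR, self.D0)
        assert u == pytest.approx(500 * 0.1 + 192)

    def test_point_behind_camera(self):
        with pytest.raises(ProjectionError):
            cg.project_to_ir([0.0, 0.0, -600.0], self.IR, self.D0)


class TestMappingChain:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        u=st.floats(0, 383),
        v=st.floats(0, 287),
        depth=st.floats(1.0, 5000.0),
    )
    def test_identity_rig_is_identity_at_any_depth(self, identity_rig, u, v, depth):
        mapped = tm.map_pixel_rgb_to_ir((u, v), identity_rig, depth)
        np.testing.assert_allclose(mapped, [u, v], atol=1e-9)

    def test_agrees_with_direct_projection_oracle(self, rng):
        """Points on the working plane: chain vs ground-truth 3D projection."""
        for seed in range(5):
            rig = tm.make_rig("realistic", seed=seed)
            n = rng.uniform(-0.12, 0.12, (100, 2))
            p3 = cg.backproject_at_depth(n, 600.0)
            px_rgb = cg.project_to_ir(p3, rig.rgb.intrinsics, rig.rgb.distortion)
            oracle = cg.project_to_ir(
                cg.transform_rgb_to_ir(p3, rig.extrinsics),
                rig.ir.intrinsics,
                rig.ir.distortion,
            )
            mapped = tm.map_pixel_rgb_to_ir(px_rgb, rig, 600.0)
            assert np.abs(mapped - oracle).max() < 1e-6

    def test_wrong_depth_offset_matches_parallax_form(self, pure_baseline_rig):
        rig = pure_baseline_rig
        f = rig.ir.intrinsics.fx
        b = rig.extrinsics.translation[0]
        p = np.array([1500.0, 700.0])
        true_map = tm.map_pixel_rgb_to_ir(p, rig, 600.0)
        for wrong in (580.0, 593.0, 611.0, 620.0):
            off = tm.map_pixel_rgb_to_ir(p, rig, wrong) - true_map
            assert abs(abs(off[0]) - f * b * abs(1 / 600 - 1 / wrong)) < 1e-9
            assert abs(off[1]) < 1e-9

    def test_out_of_bounds_flagging(self, realistic_rig):
        pts = np.array([[1500.0, 700.0], [0.0, 0.0]])
        mapped, oob = tm.map_pixel_rgb_to_ir(
            pts, realistic_rig, 600.0, return_out_of_bounds=True
        )
        assert mapped.shape == (2, 2)
        assert not oob[0]  # central point lands inside the IR frame
        assert oob[1]  # extreme RGB corner maps outside


class TestCalibration:
    BOARD = cg.CheckerboardSpec(15, 16, 25.0)

    def _recovery_errors(self, rig, est):
        rels = []
        for ch in ("rgb", "ir"):
            g, e = getattr(rig, ch).intrinsics, getattr(est, ch).intrinsics
            rels.append(
                max(
                    abs(e.fx / g.fx - 1),
                    abs(e.fy / g.fy - 1),
                    abs(e.cx / g.cx - 1),
                    abs(e.cy / g.cy - 1),
                )
            )
        terr = np.abs(
            est.extrinsics.translation - rig.extrinsics.translation
        ).max()
        return max(rels), terr

    def test_noiseless_recovery(self):
        rig = tm.make_rig("realistic", seed=11)
        obs = tm.make_checkerboard_observations(rig, self.BOARD, 10, 0.0, seed=2)
        est = tm.calibrate_rig(
            self.BOARD, obs, rgb_resolution=(2688, 1520), ir_resolution=(384, 288)
        )
        rel, terr = self._recovery_errors(rig, est)
        assert rel < 1e-3
        assert terr < 0.1
        assert est.rms_reprojection_error < 1e-8

    def test_noisy_recovery_within_one_percent(self):
        rig = tm.make_rig("realistic", seed=11)
        obs = tm.make_checkerboard_observations(rig, self.BOARD, 10, 0.1, seed=2)
        est = tm.calibrate_rig(
            self.BOARD, obs, rgb_resolution=(2688, 1520), ir_resolution=(384, 288)
        )
        rel, _ = self._recovery_errors(rig, est)
        assert rel < 0.01
        assert est.rms_reprojection_error == pytest.approx(0.1, rel=0.4)

    def test_single_pose_insufficient(self):
        rig = tm.make_rig("realistic", seed=11)
        obs = tm.make_checkerboard_observations(rig, self.BOARD, 1, 0.0, seed=2)
        with pytest.raises(InsufficientDataError):
            tm.calibrate_rig(self.BOARD, obs)

    def test_near_duplicate_poses_warn_but_return(self):
        from thermomap.errors import ConditioningWarning

        rig = tm.make_rig("realistic", seed=11)
        board = cg.CheckerboardSpec(5, 6, 25.0)
        obs = tm.make_checkerboard_observations(rig, board, 1, 0.0, seed=2)
        pose = obs.poses[0]
        jitter = np.random.default_rng(0)
        near_dupes = cg.CornerObservations(
            [
                cg.PoseCorners(
                    k,
                    pose.board_ij,
                    {
                        ch: pose.pixels[ch] + jitter.normal(0, 0.01, pose.pixels[ch].shape)
                        for ch in ("rgb", "ir")
                    },
                )
                for k in range(4)
            ]
        )
        with pytest.warns(ConditioningWarning):
            est = tm.calibrate_rig(
                board, near_dupes, rgb_resolution=(2688, 1520), ir_resolution=(384, 288)
            )
        assert est.rms_reprojection_error is not None  # best-effort result


class TestIO:
    def test_rig_json_bit_exact_round_trip(self, tmp_path, realistic_rig):
        p1, p2 = tmp_path / "rig.json", tmp_path / "rig2.json"
        tm.write_rig(realistic_rig, p1)
        r1 = tm.read_rig(p1)
        tm.write_rig(r1, p2)
        assert p1.read_text() == p2.read_text()
        assert r1.rgb.intrinsics.fx == realistic_rig.rgb.intrinsics.fx
        np.testing.assert_array_equal(
            r1.extrinsics.rotation, realistic_rig.extrinsics.rotation
        )

    def test_rig_file_accepts_homogeneous_matrix(self, tmp_path, realistic_rig):
        import json

        p = tmp_path / "rig.json"
        tm.write_rig(realistic_rig, p)
        doc = json.loads(p.read_text())
        doc["extrinsics"] = {
            "matrix_4x4": [float(v) for v in realistic_rig.extrinsics.matrix.ravel()]
        }
        p.write_text(json.dumps(doc))
        back = tm.read_rig(p)
        np.testing.assert_allclose(
            back.extrinsics.rotation, realistic_rig.extrinsics.rotation
        )
        np.testing.assert_allclose(
            back.extrinsics.translation, realistic_rig.extrinsics.translation
        )

    def test_corner_csv_round_trip(self, tmp_path, realistic_rig):
        board = cg.CheckerboardSpec(4, 5, 25.0)
        obs = tm.make_checkerboard_observations(realistic_rig, board, 3, 0.2, seed=3)
        path = tmp_path / "corners.csv"
        tm.write_corner_observations(obs, path)
        back = tm.read_corner_observations(path)
        assert back.n_poses == 3
        for a, b in zip(obs.poses, back.poses):
            np.testing.assert_array_equal(a.board_ij, b.board_ij)
            for ch in ("rgb", "ir"):
                np.testing.assert_allclose(a.pixels[ch], b.pixels[ch])
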