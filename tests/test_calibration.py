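"""Functional calibration: axis estimators, frame options, recovery."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as R

from imugait import rotations as rot
from imugait.ahrs import OrientationSeries
from imugait.calibration import (
    AmbiguousAxisError,
    CalibrationConfig,
    FunctionalAxes,
    SegmentCalibration,
    build_segment_frame,
    calibrate_trial,
    estimate_gravity_axis,
    principal_acceleration_axis,
    principal_rotation_axis,
)
from imugait.synthetic_data import (
    SENSORS,
    CalibrationMovementConfig,
    ImuRecord,
    SensorModel,
    synthesize_trial,
)


def _static_record(accel_dir, noise_sd=0.0, seed=0, n=640, fs=128.0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    accel = np.tile(np.asarray(accel_dir, dtype=float), (n, 1))
    if noise_sd:
        accel = accel + rng.normal(0, noise_sd, accel.shape)
    return ImuRecord(t, np.zeros((n, 3)), accel, "shank_R")


class TestGravityAxis:
    @pytest.mark.parametrize(
        "accel,expected",
        [([0, 0, -1.0], [0, 0, 1.0]), ([0, -1.0, 0], [0, 1.0, 0])],
    )
    def test_stated_convention(self, accel, expected):
        np.testing.assert_allclose(
            estimate_gravity_axis(_static_record(accel)), expected, atol=1e-12
        )

    def test_noisy_monte_carlo_within_02_deg(self):
        errs = []
        for seed in range(50):
            axis = estimate_gravity_axis(
                _static_record([0, 0, -1.0], noise_sd=0.02, seed=seed)
            )
            errs.append(np.degrees(np.arccos(np.clip(axis @ [0, 0, 1.0], -1, 1))))
        assert max(errs) < 0.2

    def test_non_static_rejected(self):
        rec = _static_record([0, 0, -1.0])
        rec.gyro[:, 1] = np.deg2rad(8.0)
        with pytest.raises(ValueError, match="static"):
            estimate_gravity_axis(rec)


class TestRotationPca:
    def test_rank_one_cloud(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(500, 1)) * 2.0
        gyro = s * np.array([1.0, 0, 0])
        # make the first-half signed integral positive for the sign rule
        gyro[:250] = np.abs(gyro[:250])
        axis, ev = principal_rotation_axis(gyro)
        np.testing.assert_allclose(axis, [1.0, 0, 0], atol=1e-12)
        assert ev == pytest.approx(1.0)

    def test_noisy_axis_recovery_within_1_deg(self):
        u = np.array([1.0, 0, 0.1])
        u /= np.linalg.norm(u)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.linspace(0, 1, 600)
            rate = 2.0 * np.sin(np.pi * t)  # rad/s, positive first half
            gyro = rate[:, None] * u
            noise_sd = 0.05 * np.sqrt(np.mean(rate**2))
            gyro = gyro + rng.normal(0, noise_sd, gyro.shape)
            axis, _ = principal_rotation_axis(gyro)
            errs.append(np.degrees(np.arccos(np.clip(abs(axis @ u), -1, 1))))
        assert max(errs) < 1.0

    def test_sign_follows_first_half_rotation(self):
        t = np.linspace(0, 1, 400)
        rate = np.sin(2 * np.pi * t)  # positive then negative
        gyro = rate[:, None] * np.array([0.0, 1.0, 0])
        axis, _ = principal_rotation_axis(gyro)
        assert axis[1] > 0
        axis2, _ = principal_rotation_axis(-gyro)
        assert axis2[1] < 0

    def test_isotropic_cloud_is_ambiguous(self):
        rng = np.random.default_rng(3)
        gyro = rng.normal(0, 1.0, size=(2000, 3))
        with pytest.raises(AmbiguousAxisError):
            principal_rotation_axis(gyro)

    def test_static_input_rejected(self):
        with pytest.raises(ValueError, match="motion"):
            principal_rotation_axis(np.zeros((300, 3)) + 1e-5)


class TestAccelerationPca:
    def _series(self, n, fs=128.0, quat=None):
        t = np.arange(n) / fs
        q = np.tile([1.0, 0, 0, 0], (n, 1)) if quat is None else np.tile(quat, (n, 1))
        return t, OrientationSeries(t, q, np.zeros(3))

    def test_pure_lab_y_acceleration(self):
        n = 512
        t, orient = self._series(n)
        a = 0.3 * np.cos(2 * np.pi * 1.0 * t)  # positive net velocity first
        accel = np.stack([np.zeros(n), a, -np.ones(n)], axis=1)
        rec = ImuRecord(t, np.zeros((n, 3)), accel, "shank_R")
        axis, ev = principal_acceleration_axis(rec, orient)
        np.testing.assert_allclose(axis, [0, 1.0, 0], atol=1e-9)
        assert ev > 0.99

    def test_yawed_sensor_equivariance(self):
        n = 512
        t, _ = self._series(n)
        a = 0.3 * np.cos(2 * np.pi * 1.0 * t)
        a_lab = np.stack([np.zeros(n), a, -np.ones(n)], axis=1)
        q_yaw = rot.axis_angle(np.array([0.0, 0, 1]), 30.0)
        Ryaw = rot.quat_to_matrix(q_yaw)
        accel_sensor = a_lab @ Ryaw  # R^T a for each row
        rec = ImuRecord(t, np.zeros((n, 3)), accel_sensor, "shank_R")
        orient = OrientationSeries(t, np.tile(q_yaw, (n, 1)), np.zeros(3))
        axis, _ = principal_acceleration_axis(rec, orient)
        np.testing.assert_allclose(axis, Ryaw.T @ [0, 1.0, 0], atol=1e-9)

    def test_near_vertical_direction_rejected(self):
        n = 512
        t, orient = self._series(n)
        a = 0.3 * np.cos(2 * np.pi * 1.0 * t)
        accel = np.stack([np.zeros(n), np.zeros(n), -1.0 + a], axis=1)
        rec = ImuRecord(t, np.zeros((n, 3)), accel, "shank_R")
        with pytest.raises(ValueError, match="vertical"):
            principal_acceleration_axis(rec, orient)

    def test_walking_shank_anterior_axis_within_3_deg(self, misaligned_model):
        trial = synthesize_trial(
            CalibrationMovementConfig("walking", wobble_sd_deg=0,
                                      contamination_deg=0),
            misaligned_model,
            seed=21,
        )
        calib = calibrate_trial(trial.records, "walking")["shank_R"]
        anterior_true = misaligned_model.misalignment_of("shank_R").T @ [0, 1.0, 0]
        ang = np.degrees(
            np.arccos(
                np.clip(calib.axes.functional_axis_sensor @ anterior_true, -1, 1)
            )
        )
        # the residual is the physical tilt of the shank's principal
        # acceleration direction away from the anterior axis, not noise
        assert ang < 5.0


class TestBuildSegmentFrame:
    def _axes(self, g, r, source="rotation_pca"):
        g = np.asarray(g, float); g = g / np.linalg.norm(g)
        r = np.asarray(r, float); r = r / np.linalg.norm(r)
        return FunctionalAxes(g, r, source, 1.0)

    def test_gravity_aligned_projects_functional_axis(self):
        axes = self._axes([0, 0, 1.0], [1.0, 0, 0.1])
        R_ = build_segment_frame(axes, "gravity_aligned", "lateral")
        np.testing.assert_allclose(R_[0], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(R_[1], [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(R_[2], [0, 0, 1], atol=1e-12)

    def test_orthogonal_axes_make_options_agree(self):
        axes = self._axes([0, 0, 1.0], [1.0, 0, 0])
        a = build_segment_frame(axes, "gravity_aligned", "lateral")
        b = build_segment_frame(axes, "functional_aligned", "lateral")
        np.testing.assert_allclose(a, b, atol=1e-9)
        np.testing.assert_allclose(a, np.eye(3), atol=1e-12)

    def test_functional_aligned_keeps_axis_exact(self):
        r = np.array([1.0, 0, 0.1]); r /= np.linalg.norm(r)
        axes = self._axes([0, 0, 1.0], r)
        R_ = build_segment_frame(axes, "functional_aligned", "lateral")
        np.testing.assert_allclose(R_[0], r, atol=1e-12)
        tilt = np.degrees(np.arccos(np.clip(R_[2] @ [0, 0, 1.0], -1, 1)))
        assert tilt == pytest.approx(np.degrees(np.arctan(0.1)), abs=1e-9)

    def test_anterior_role(self):
        axes = self._axes([0, 0, 1.0], [0, 1.0, 0.1], "acceleration_pca")
        R_ = build_segment_frame(axes, "gravity_aligned", "anterior")
        np.testing.assert_allclose(R_[1], [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(R_[0], [1, 0, 0], atol=1e-12)

    def test_near_parallel_axes_rejected(self):
        axes = self._axes([0, 0, 1.0], [0.1, 0, 1.0])
        with pytest.raises(ValueError, match="ill-conditioned"):
            build_segment_frame(axes)

    def test_produced_frames_are_rotations(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            g = rng.normal(size=3); g /= np.linalg.norm(g)
            r = rng.normal(size=3); r /= np.linalg.norm(r)
            if abs(g @ r) > 0.7:
                continue
            for option in ("gravity_aligned", "functional_aligned"):
                for role in ("lateral", "anterior"):
                    R_ = build_segment_frame(self._axes(g, r), option, role)
                    np.testing.assert_allclose(R_.T @ R_, np.eye(3), atol=1e-9)
                    assert np.linalg.det(R_) == pytest.approx(1.0, abs=1e-9)


class TestCalibrate:
    def test_identity_mounting_recovered(self, noise_free_model):
        trial = synthesize_trial(
            CalibrationMovementConfig("tilted", wobble_sd_deg=0,
                                      contamination_deg=0),
            noise_free_model,
            seed=0,
        )
        for calib in calibrate_trial(trial.records, "tilted").values():
            assert rot.geodesic_angle_deg(
                calib.R_sensor_to_segment, np.eye(3)
            ) < 0.1

    def test_misalignment_recovered(self, ideal_tilted_trial, misaligned_model):
        for sid, calib in calibrate_trial(
            ideal_tilted_trial.records, "tilted"
        ).items():
            err = rot.geodesic_angle_deg(
                calib.R_sensor_to_segment, misaligned_model.misalignment_of(sid)
            )
            assert err < 0.5

    def test_squat_degrades_shank_vs_tilted_same_seed(self):
        rng = np.random.default_rng(1)
        model = SensorModel.random(rng, max_misalignment_deg=20)
        errs = {}
        for kind, exc in (("tilted", None), ("squat", None)):
            trial = synthesize_trial(
                CalibrationMovementConfig(kind), model, seed=55
            )
            calib = calibrate_trial(trial.records, kind)["shank_R"]
            errs[kind] = rot.geodesic_angle_deg(
                calib.R_sensor_to_segment, model.misalignment_of("shank_R")
            )
        assert errs["squat"] > errs["tilted"]

    def test_equivariance_under_sensor_rotation(self, ideal_tilted_trial):
        """Pre-rotating raw signals by Q right-multiplies the result by Q^-1."""
        Q = rot.quat_to_matrix(
            rot.axis_angle(np.array([0.36, 0.48, 0.8]), 25.0)
        )
        rec = ideal_tilted_trial.records["thigh_R"]
        base = calibrate_trial(
            ideal_tilted_trial.records, "tilted"
        )["thigh_R"].R_sensor_to_segment
        rotated = ImuRecord(rec.time, rec.gyro @ Q, rec.accel @ Q, "thigh_R")
        # v' = Q^T v  <=>  the new sensor frame is the old one rotated by Q
        records = dict(ideal_tilted_trial.records)
        records["thigh_R"] = rotated
        out = calibrate_trial(records, "tilted")["thigh_R"].R_sensor_to_segment
        np.testing.assert_allclose(out, base @ Q, atol=np.deg2rad(0.1))

    def test_monotone_degradation_with_shrinking_excursion(self):
        rng = np.random.default_rng(2)
        model = SensorModel.random(rng, max_misalignment_deg=15)
        medians = []
        for exc in (60.0, 30.0, 15.0, 5.0):
            errs = []
            for rep in range(8):
                # shrink the distal excursion at fixed execution noise: the
                # thigh keeps moving, so phase segmentation stays valid and
                # only the shank's amplitude-to-noise ratio degrades
                cfg = CalibrationMovementConfig(
                    "tilted",
                    excursion_deg={"pelvis": 45.0, "thigh": 60.0,
                                   "shank": exc, "foot": exc},
                    wobble_sd_deg=0.5,
                    contamination_deg=0.5,
                )
                trial = synthesize_trial(cfg, model, seed=1000 + rep)
                calib = calibrate_trial(trial.records, "tilted")["shank_L"]
                errs.append(
                    rot.geodesic_angle_deg(
                        calib.R_sensor_to_segment,
                        model.misalignment_of("shank_L"),
                    )
                )
            medians.append(np.median(errs))
        assert all(b >= a - 1e-9 for a, b in zip(medians, medians[1:]))

    def test_json_round_trip(self, ideal_tilted_trial, tmp_path):
        calib = calibrate_trial(ideal_tilted_trial.records, "tilted")["foot_R"]
        path = tmp_path / "calib.json"
        calib.to_json(path)
        back = SegmentCalibration.from_json(path)
        np.testing.assert_allclose(
            back.R_sensor_to_segment, calib.R_sensor_to_segment, atol=1e-9
        )
        assert back.movement_kind == "tilted"
        assert back.axes.axis_source == "rotation_pca"

    def test_unknown_kind_rejected(self, ideal_tilted_trial):
        with pytest.raises(ValueError, match="kind"):
            calibrate_trial(ideal_tilted_trial.records, "hopping")
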