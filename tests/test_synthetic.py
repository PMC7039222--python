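"""Synthetic gait/IMU generator: waveforms, kinematics, sensor model."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as R

from imugait import rotations as rot
from imugait.synthetic_data import (
    JOINTS,
    SENSORS,
    CalibrationMovementConfig,
    GaitWaveformConfig,
    ImuRecord,
    SensorModel,
    angular_rates_interval,
    continuous_plane_rom,
    default_rom_table,
    forward_kinematics,
    generate_calibration_movement,
    generate_gait_trajectory,
    simulate_imu,
    synthesize_trial,
)


class TestGaitWaveforms:
    def test_configured_rom_achieved_exactly(self):
        cfg = GaitWaveformConfig()
        cfg.rom_deg[("knee_R", "sagittal")] = 73.0
        assert continuous_plane_rom(cfg, "knee_R", "sagittal") == pytest.approx(
            73.0, abs=1e-6
        )

    def test_zero_amplitudes_give_constant_angles(self):
        cfg = GaitWaveformConfig(
            rom_deg={k: 0.0 for k in default_rom_table()}, n_strides=2
        )
        traj = generate_gait_trajectory(cfg)
        for joint in JOINTS:
            a = traj["angles"][joint]
            assert np.ptp(a[:, 1]) == pytest.approx(0.0, abs=1e-12)
            assert np.ptp(a[:, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_default_hip_sagittal_rom_near_typical(self):
        """Default configuration targets ~50 deg of hip flexion-extension."""
        trial = synthesize_trial(
            GaitWaveformConfig(n_strides=4),
            SensorModel(gyro_noise_sd=0, accel_noise_sd=0),
            seed=0,
        )
        rom = np.ptp(trial.joint_angles["hip_R"][trial.movement_slice, 0])
        assert abs(rom - 50.4) < 2.0

    def test_non_positive_cadence_rejected(self):
        with pytest.raises(ValueError, match="cadence"):
            generate_gait_trajectory(
                GaitWaveformConfig(cadence_strides_per_s=0.0)
            )


class TestForwardKinematics:
    def _zero_angles(self, n=10):
        return {j: np.zeros((n, 3)) for j in JOINTS}

    def test_static_posture_is_identity(self):
        Rs, _ = forward_kinematics(self._zero_angles())
        for seg, stack in Rs.items():
            np.testing.assert_allclose(
                stack, np.broadcast_to(np.eye(3), stack.shape), atol=1e-12
            )

    def test_single_hip_flexion(self):
        angles = self._zero_angles()
        angles["hip_R"][:, 0] = 40.0
        Rs, _ = forward_kinematics(angles)
        np.testing.assert_allclose(Rs["pelvis"][0], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(Rs["thigh_R"][0], rot.rotx(40.0), atol=1e-12)

    def test_round_trip_joint_angle_recovery(self):
        traj = generate_gait_trajectory(GaitWaveformConfig(n_strides=2))
        Rs, _ = forward_kinematics(traj["angles"])
        rel = np.einsum("nji,njk->nik", Rs["thigh_R"], Rs["shank_R"])
        back = rot.cardan_series_from_matrices(rel)
        np.testing.assert_allclose(
            back, traj["angles"]["knee_R"], atol=1e-6
        )

    def test_mismatched_lengths_rejected(self):
        angles = self._zero_angles()
        angles["knee_L"] = np.zeros((7, 3))
        with pytest.raises(ValueError, match="time base"):
            forward_kinematics(angles)


class TestSimulateImu:
    def test_static_trial_reads_gravity_only(self, walk_trial):
        sl = walk_trial.static_slice
        for rec in walk_trial.records.values():
            np.testing.assert_allclose(rec.gyro[sl], 0.0, atol=1e-12)
            np.testing.assert_allclose(
                rec.accel[sl], np.tile([0, 0, -1.0], (sl.stop, 1)), atol=1e-12
            )

    def test_constant_rate_rotation_reads_10_dps(self):
        # hand-built trial: every segment rotates about X at 10 deg/s
        n, fs = 256, 128.0
        t = np.arange(n) / fs
        theta = 10.0 * t
        stack = np.stack([rot.rotx(a) for a in theta])
        trial_angles = {j: np.zeros((n, 3)) for j in JOINTS}
        trial_angles["pelvis"][:, 0] = theta
        Rs, pos = forward_kinematics(trial_angles)
        from imugait.synthetic_data import SyntheticTrial

        trial = SyntheticTrial(
            time=t, fs=fs, segment_rot=Rs, sensor_pos=pos,
            joint_angles=trial_angles, static_slice=slice(0, 1),
            movement_slice=slice(0, n),
        )
        recs = simulate_imu(
            trial, SensorModel(gyro_noise_sd=0, accel_noise_sd=0, fs=fs)
        )
        gyro_dps = np.degrees(recs["L5"].gyro[5:])
        np.testing.assert_allclose(gyro_dps[:, 0], 10.0, atol=1e-6)
        np.testing.assert_allclose(gyro_dps[:, 1:], 0.0, atol=1e-6)

    def test_noise_free_record_integrates_back_to_truth(self, noise_free_model):
        """Differentiate-then-integrate consistency over 20 s at 128 Hz."""
        trial = synthesize_trial(
            GaitWaveformConfig(n_strides=14), noise_free_model, seed=5
        )
        assert trial.time[-1] >= 20.0
        rec = trial.records["foot_R"]
        q = rot.matrix_to_quat(trial.segment_rot["foot_R"][0])
        dt = 1.0 / trial.fs
        worst = 0.0
        for k in range(1, trial.n_samples):
            q = rot.quat_normalize(
                rot.quat_multiply(q, rot.quat_from_rotvec(rec.gyro[k] * dt)),
                canonical=False,
            )
            if k % 64 == 0:
                worst = max(
                    worst,
                    rot.geodesic_angle_deg(
                        rot.quat_normalize(q), trial.segment_rot["foot_R"][k]
                    ),
                )
        assert worst < 0.05

    def test_gyro_noise_scaling(self, noise_free_model):
        trial = synthesize_trial(
            GaitWaveformConfig(n_strides=25), noise_free_model, seed=6
        )
        base = SensorModel(gyro_noise_sd=0.01, accel_noise_sd=0.0)
        double = SensorModel(gyro_noise_sd=0.02, accel_noise_sd=0.0)
        clean = trial.records["shank_L"].gyro
        r1 = simulate_imu(trial, base, seed=10)["shank_L"].gyro
        r2 = simulate_imu(trial, double, seed=11)["shank_L"].gyro
        assert clean.size >= 1e4
        sd1 = np.std(r1 - clean)
        sd2 = np.std(r2 - clean)
        assert sd2 / sd1 == pytest.approx(2.0, rel=0.1)

    def test_static_accel_magnitude_within_noise(self):
        model = SensorModel(gyro_noise_sd=0.0, accel_noise_sd=0.02)
        trial = synthesize_trial(GaitWaveformConfig(n_strides=2), model, seed=8)
        sl = trial.static_slice
        mags = np.linalg.norm(trial.records["L5"].accel[sl], axis=1)
        n = sl.stop
        assert abs(mags.mean() - 1.0) < 3 * 0.02 / np.sqrt(n) * np.sqrt(3)

    def test_rate_mismatch_rejected(self, walk_trial):
        with pytest.raises(ValueError, match="rate"):
            simulate_imu(walk_trial, SensorModel(fs=100.0))


class TestCalibrationMovements:
    def test_static_phase_has_zero_angular_velocity(self):
        trial = generate_calibration_movement(
            CalibrationMovementConfig("extension"), seed=0
        )
        sl = trial.static_slice
        for seg, Rs in trial.segment_rot.items():
            w = angular_rates_interval(Rs, trial.fs)
            assert np.abs(w[sl][1:]).max() < 1e-12

    def test_ideal_tilted_rotates_about_segment_x_only(self):
        cfg = CalibrationMovementConfig(
            "tilted", wobble_sd_deg=0.0, contamination_deg=0.0
        )
        trial = generate_calibration_movement(cfg, seed=0)
        w = angular_rates_interval(trial.segment_rot["thigh_L"], trial.fs)
        mv = trial.movement_slice
        assert np.abs(w[mv, 1:]).max() < 1e-9
        assert np.degrees(np.abs(w[mv, 0]).max()) > 10.0

    def test_squat_moves_shank_less_than_thigh(self):
        cfg = CalibrationMovementConfig("squat")
        assert cfg.excursion_deg["shank"] < cfg.excursion_deg["thigh"]
        assert cfg.excursion_deg["foot"] < cfg.excursion_deg["thigh"]
        with pytest.raises(ValueError, match="squat"):
            CalibrationMovementConfig(
                "squat",
                excursion_deg={"pelvis": 30, "thigh": 20, "shank": 40, "foot": 5},
            )

    def test_walking_kind_delegates_to_gait_generator(self):
        trial = generate_calibration_movement(
            CalibrationMovementConfig("walking", n_strides=2), seed=0
        )
        assert trial.kind == "walking"
        assert len(trial.stride_bounds) == 2

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            CalibrationMovementConfig("jumping")

    def test_execution_noise_is_seeded(self):
        cfg = CalibrationMovementConfig("tilted")
        a = generate_calibration_movement(cfg, seed=4)
        b = generate_calibration_movement(cfg, seed=4)
        c = generate_calibration_movement(cfg, seed=5)
        np.testing.assert_array_equal(
            a.segment_rot["foot_R"], b.segment_rot["foot_R"]
        )
        assert np.abs(a.segment_rot["foot_R"] - c.segment_rot["foot_R"]).max() > 1e-6


class TestTrialConsistency:
    def test_joint_angles_match_segment_orientations(self, walk_trial):
        from imugait.synthetic_data import JOINT_CHAIN

        for joint, (prox, dist) in JOINT_CHAIN.items():
            Rd = walk_trial.segment_rot[dist]
            rel = Rd if prox is None else np.einsum(
                "nji,njk->nik", walk_trial.segment_rot[prox], Rd
            )
            back = rot.cardan_series_from_matrices(rel)
            np.testing.assert_allclose(
                back, walk_trial.joint_angles[joint], atol=1e-6
            )

    def test_trial_is_bit_reproducible(self, noise_free_model):
        model = SensorModel()  # default noise on
        a = synthesize_trial(GaitWaveformConfig(n_strides=2), model, seed=77)
        b = synthesize_trial(GaitWaveformConfig(n_strides=2), model, seed=77)
        for sid in SENSORS:
            np.testing.assert_array_equal(a.records[sid].gyro, b.records[sid].gyro)
            np.testing.assert_array_equal(a.records[sid].accel, b.records[sid].accel)


class TestIO:
    def test_imu_record_csv_round_trip(self, walk_trial, tmp_path):
        rec = walk_trial.records["thigh_R"]
        path = tmp_path / "rec.csv"
        rec.to_csv(path)
        back = ImuRecord.from_csv(path, "thigh_R")
        np.testing.assert_allclose(back.gyro, rec.gyro, atol=1e-12)
        np.testing.assert_allclose(back.accel, rec.accel, atol=1e-12)

    def test_trial_hdf5_round_trip(self, tmp_path):
        model = SensorModel.random(np.random.default_rng(0))
        trial = synthesize_trial(GaitWaveformConfig(n_strides=2), model, seed=9)
        path = tmp_path / "trial.h5"
        trial.to_hdf5(path)
        back = trial.from_hdf5(path)
        np.testing.assert_array_equal(
            back.segment_rot["shank_R"], trial.segment_rot["shank_R"]
        )
        np.testing.assert_array_equal(
            back.records["L5"].accel, trial.records["L5"].accel
        )
        assert back.static_slice == trial.static_slice
        np.testing.assert_allclose(
            back.sensor_model.misalignment_of("foot_L"),
            model.misalignment_of("foot_L"),
        )

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 0.1, 0.3])
        with pytest.raises(ValueError, match="uniform"):
            ImuRecord(t, np.zeros((3, 3)), np.zeros((3, 3)), "L5")
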