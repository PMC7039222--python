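import numpy as np
import pytest

from imugait.synthetic_data import (
    CalibrationMovementConfig,
    GaitWaveformConfig,
    SensorModel,
    synthesize_trial,
)


@pytest.fixture(scope="session")
def noise_free_model():
    return SensorModel(gyro_noise_sd=0.0, accel_noise_sd=0.0)


@pytest.fixture(scope="session")
def misaligned_model():
    """Noise-free sensor model with random mounting errors up to 25 deg."""
    rng = np.random.default_rng(42)
    return SensorModel.random(
        rng,
        max_misalignment_deg=25.0,
        gyro_noise_sd=0.0,
        gyro_bias_sd=0.0,
        accel_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def walk_trial(noise_free_model):
    """Short noise-free walking trial with aligned sensors."""
    return synthesize_trial(
        GaitWaveformConfig(n_strides=3), noise_free_model, seed=1
    )


@pytest.fixture(scope="session")
def misaligned_walk_trial(misaligned_model):
    return synthesize_trial(
        GaitWaveformConfig(n_strides=3), misaligned_model, seed=3
    )


@pytest.fixture(scope="session")
def ideal_tilted_trial(misaligned_model):
    """Perfectly executed tilted-to-stand calibration, misaligned sensors."""
    cfg = CalibrationMovementConfig(
        "tilted", wobble_sd_deg=0.0, contamination_deg=0.0
    )
    return synthesize_trial(cfg, misaligned_model, seed=2)
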