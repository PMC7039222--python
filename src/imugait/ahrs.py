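"""Mahony-type complementary attitude filter (gyro + accelerometer, no
magnetometer).

The filter keeps a unit quaternion ``q`` mapping sensor-frame coordinates to
lab-frame coordinates and corrects the integrated gyroscope rate with the
cross product between the measured specific-force direction and the gravity
direction predicted by ``q``.  Without a magnetometer the heading (rotation
about the lab vertical) is unobservable: it is zeroed at initialization and
then evolves by gyro integration alone; reconciling heading across sensors is
the calibration/kinematics layer's job.

Default gains: ``kp = 0.5 1/s`` gives a ~2 s attitude time constant at
128 Hz — large enough that a 0.5 deg/s gyro bias settles to ~1 deg of tilt
error, small enough that ~2 Hz walking accelerations are attenuated to a few
percent.  ``ki`` defaults to 0 (no bias estimator); both are configuration.

Integration advances the quaternion by the exponential of one gyro sample
per sampling interval — exact for a constant rate within a step, and the
exact inverse of the synthetic generator's interval-average rate encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rotations import quat_from_rotvec, quat_multiply, quat_normalize, quat_rotate
from .synthetic_data import ImuRecord

__all__ = [
    "AhrsConfig",
    "OrientationSeries",
    "init_from_static",
    "mahony_step",
    "estimate_orientation",
]

#: lab "up" direction (lab Z points down), i.e. the direction a static
#: accelerometer's specific force points in lab coordinates.
_UP = np.array([0.0, 0.0, -1.0])


@dataclass
class AhrsConfig:
    kp: float = 0.5                 # proportional gain, 1/s
    ki: float = 0.0                 # integral gain, 1/s^2
    static_window_s: float = 5.0    # initialization window
    static_gyro_rms_max_dps: float = 2.0  # motion rejection threshold
    accel_min_g: float = 0.01       # free-fall guard

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0:
            raise ValueError("gains must be non-negative")


@dataclass
class OrientationSeries:
    """Per-sample lab<-sensor orientations plus the final integral state."""

    time: np.ndarray
    quat: np.ndarray                # (N, 4) scalar-first, unit, canonical
    integral_error: np.ndarray

    def __len__(self) -> int:
        return len(self.time)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "qw": self.quat[:, 0], "qx": self.quat[:, 1],
                "qy": self.quat[:, 2], "qz": self.quat[:, 3],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OrientationSeries":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            quat_normalize(df[["qw", "qx", "qy", "qz"]].to_numpy()),
            np.zeros(3),
        )


def init_from_static(
    record: ImuRecord,
    window_s: float = 5.0,
    gyro_rms_max_dps: float = 2.0,
) -> np.ndarray:
    """Initial lab<-sensor orientation from a static standing window.

    The mean accelerometer direction (specific force, pointing up) is rotated
    onto the lab up direction by the shortest rotation, which leaves the
    heading (rotation about lab Z) at zero.
    """
    n = min(len(record.time), max(int(round(window_s * record.fs)), 1))
    if record.time[n - 1] - record.time[0] < 1.0 - 1e-9:
        raise ValueError("static window must contain at least 1 s of samples")
    gyro = record.gyro[:n]
    accel = record.accel[:n]
    gyro_rms = np.degrees(np.sqrt(np.mean(np.sum(gyro**2, axis=1))))
    if gyro_rms > gyro_rms_max_dps:
        raise ValueError(
            f"window is not static: gyro rms {gyro_rms:.2f} deg/s exceeds "
            f"{gyro_rms_max_dps} deg/s"
        )
    mean_a = accel.mean(axis=0)
    mag = np.linalg.norm(mean_a)
    if abs(mag - 1.0) > 0.1:
        raise ValueError(
            f"static window mean |accel| = {mag:.3f} g is not within 0.1 g of 1 g"
        )
    a_hat = mean_a / mag
    # shortest rotation taking the sensor-frame up measurement to lab up
    v = np.cross(a_hat, _UP)
    c = float(np.dot(a_hat, _UP))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        # antiparallel: rotate 180 deg about any horizontal axis
        return np.array([0.0, 1.0, 0.0, 0.0])
    angle = np.arctan2(np.linalg.norm(v), c)
    axis = v / np.linalg.norm(v)
    return quat_normalize(quat_from_rotvec(angle * axis))


def mahony_step(
    q: np.ndarray,
    gyro: np.ndarray,
    accel: np.ndarray,
    dt: float,
    cfg: AhrsConfig,
    integral: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One filter update; returns the new quaternion and integral state.

    The error term is ``e = a_hat x v_hat`` where ``a_hat`` is the measured
    specific-force direction and ``v_hat = R(q)^T (0,0,-1)`` the up direction
    predicted by the current attitude.  The corrected rate
    ``gyro + kp e + ki \\int e`` is integrated with the quaternion
    exponential.  Accelerometer magnitudes below ``accel_min_g`` skip the
    correction (free-fall guard).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if integral is None:
        integral = np.zeros(3)
    omega = np.asarray(gyro, dtype=float)
    a = np.asarray(accel, dtype=float)
    a_norm = np.linalg.norm(a)
    if a_norm >= cfg.accel_min_g:
        a_hat = a / a_norm
        # predicted up direction in sensor coordinates: R^T (0,0,-1)
        w, x, y, z = q
        v_hat = np.array(
            [
                -2.0 * (x * z - w * y),
                -2.0 * (y * z + w * x),
                -(w * w - x * x - y * y + z * z),
            ]
        )
        e = np.cross(a_hat, v_hat)
        if cfg.ki > 0:
            integral = integral + cfg.ki * e * dt
        omega = omega + cfg.kp * e + integral
    q_new = quat_multiply(q, quat_from_rotvec(omega * dt))
    return quat_normalize(q_new), integral


def estimate_orientation(
    record: ImuRecord,
    q0: np.ndarray | None = None,
    cfg: AhrsConfig | None = None,
) -> OrientationSeries:
    """Run the filter over a whole record (deterministic given inputs).

    ``q0`` defaults to :func:`init_from_static` on the configured leading
    window.  Each gyro sample is integrated over one sampling interval with
    the quaternion exponential (exact for a constant rate within the step).
    """
    cfg = cfg or AhrsConfig()
    bad = ~(np.isfinite(record.gyro).all(axis=1) & np.isfinite(record.accel).all(axis=1))
    if bad.any():
        raise ValueError(f"NaN/inf samples at indices {np.nonzero(bad)[0][:5]}")
    if q0 is None:
        q0 = init_from_static(
            record, cfg.static_window_s, cfg.static_gyro_rms_max_dps
        )
    n = len(record.time)
    quats = np.empty((n, 4))
    quats[0] = quat_normalize(q0)
    q = quats[0]
    integral = np.zeros(3)
    dt = 1.0 / record.fs
    gyro = record.gyro
    accel = record.accel
    for k in range(1, n):
        q, integral = mahony_step(q, gyro[k], accel[k], dt, cfg, integral)
        quats[k] = q
    return OrientationSeries(record.time, quat_normalize(quats), integral)


def tilt_error_deg(q: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Heading-independent attitude (roll/pitch) error between quaternions.

    The angle between the lab up direction as seen by each orientation —
    insensitive to the unobservable rotation about lab Z.
    """
    from .rotations import quat_conjugate

    up_est = quat_rotate(quat_conjugate(quat_normalize(np.atleast_2d(q))), _UP)
    up_true = quat_rotate(quat_conjugate(quat_normalize(np.atleast_2d(q_true))), _UP)
    dot = np.clip(np.sum(up_est * up_true, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(dot))
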