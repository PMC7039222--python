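"""Functional sensor-to-segment calibration.

A functional calibration aligns an arbitrarily mounted sensor frame with
anatomically meaningful segment axes using two measured directions:

* the **gravity axis** ``g`` — lab-down expressed in sensor coordinates,
  measured during an upright static posture (the segment's vertical axis);
* a **functional axis** ``r`` — for the tilted / extension / squat movements,
  the principal rotation axis of the sagittal excursion (uncentered
  second-moment PCA of the gyroscope sample cloud, assigned to the
  medio-lateral segment axis); for the walking movement, the principal
  horizontal acceleration direction in the lab frame (mean-centered PCA of
  gravity-compensated lab-frame accelerations, assigned to the anterior
  segment axis).

Two frame-construction options resolve the (generally non-orthogonal) pair
into a segment frame: ``gravity_aligned`` keeps the vertical axis exactly on
``g`` and takes the functional axis' orthogonal complement, while
``functional_aligned`` keeps the functional axis exact and takes the
orthogonal axis closest to gravity as vertical.  When ``g`` and ``r`` are
exactly orthogonal the two options coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ahrs import AhrsConfig, OrientationSeries, estimate_orientation, init_from_static
from .rotations import assert_rotation, matrix_to_quat, quat_to_matrix, quat_rotate
from .synthetic_data import ImuRecord

__all__ = [
    "AmbiguousAxisError",
    "CalibrationConfig",
    "FunctionalAxes",
    "SegmentCalibration",
    "estimate_gravity_axis",
    "principal_rotation_axis",
    "principal_acceleration_axis",
    "build_segment_frame",
    "calibrate",
    "segment_phases",
]

ROTATION_KINDS = ("tilted", "extension", "squat")
FRAME_OPTIONS = ("gravity_aligned", "functional_aligned")


class AmbiguousAxisError(ValueError):
    """The movement is not planar enough to define a unique principal axis."""


@dataclass
class CalibrationConfig:
    motion_threshold_dps: float = 10.0   # movement-phase segmentation
    hysteresis_s: float = 0.25
    min_movement_s: float = 1.0
    pca_min_rms_dps: float = 2.0         # reject truly static input to PCA
    static_window_s: float = 5.0
    eig_ambiguity_ratio: float = 0.95    # lambda2/lambda1 above this -> error
    vertical_cone_deg: float = 10.0      # accel-PCA degeneracy guard
    min_axis_separation_deg: float = 15.0
    ahrs: AhrsConfig = field(default_factory=AhrsConfig)


@dataclass
class FunctionalAxes:
    """The two measured directions a calibration is built from.

    Both are unit vectors in sensor coordinates at the static reference;
    ``explained_variance`` is the fraction of (second-moment or centered)
    variance captured by the principal direction, recorded for quality
    control.
    """

    gravity_axis_sensor: np.ndarray
    functional_axis_sensor: np.ndarray
    axis_source: str  # rotation_pca | acceleration_pca
    explained_variance: float

    def __post_init__(self) -> None:
        for v in (self.gravity_axis_sensor, self.functional_axis_sensor):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("calibration axes must be unit-norm")


@dataclass
class SegmentCalibration:
    """Sensor-to-segment rotation with provenance."""

    sensor_id: str
    R_sensor_to_segment: np.ndarray   # v_segment = R @ v_sensor
    frame_option: str
    movement_kind: str
    axes: FunctionalAxes

    def __post_init__(self) -> None:
        assert_rotation(self.R_sensor_to_segment)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sensor_id": self.sensor_id,
            "quaternion_wxyz": matrix_to_quat(self.R_sensor_to_segment).tolist(),
            "frame_option": self.frame_option,
            "movement_kind": self.movement_kind,
            "gravity_axis_sensor": self.axes.gravity_axis_sensor.tolist(),
            "functional_axis_sensor": self.axes.functional_axis_sensor.tolist(),
            "axis_source": self.axes.axis_source,
            "explained_variance": self.axes.explained_variance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentCalibration":
        return cls(
            sensor_id=d["sensor_id"],
            R_sensor_to_segment=quat_to_matrix(np.asarray(d["quaternion_wxyz"])),
            frame_option=d["frame_option"],
            movement_kind=d["movement_kind"],
            axes=FunctionalAxes(
                np.asarray(d["gravity_axis_sensor"]),
                np.asarray(d["functional_axis_sensor"]),
                d["axis_source"],
                d["explained_variance"],
            ),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    @classmethod
    def from_json(cls, path) -> "SegmentCalibration":
        with open(path) as f:
            return cls.from_dict(json.load(f))


# ---------------------------------------------------------------------------
# phase segmentation
# ---------------------------------------------------------------------------

def segment_phases(
    record: ImuRecord,
    cfg: CalibrationConfig | None = None,
    magnitude_dps: np.ndarray | None = None,
) -> tuple[slice, slice]:
    """Split a calibration record into (static, movement) sample slices.

    Movement is where the gyro magnitude exceeds ``motion_threshold_dps``;
    gaps shorter than ``hysteresis_s`` are bridged.  The static slice is the
    quiet leading portion.  ``magnitude_dps`` overrides the per-record gyro
    magnitude — used to segment all sensors of a trial on a shared timeline
    (the distal segments of a squat move too slowly to trip the threshold on
    their own even though the body is moving).
    """
    cfg = cfg or CalibrationConfig()
    if magnitude_dps is None:
        mag_dps = np.degrees(np.linalg.norm(record.gyro, axis=1))
    else:
        mag_dps = np.asarray(magnitude_dps, dtype=float)
    active = mag_dps > cfg.motion_threshold_dps
    if not active.any():
        raise ValueError("no movement phase found (gyro never above threshold)")
    idx = np.nonzero(active)[0]
    gap = int(round(cfg.hysteresis_s * record.fs))
    # bridge short gaps: movement = [first, last] active with hysteresis
    start, stop = int(idx[0]), int(idx[-1]) + 1
    static_stop = max(start - gap, 1)
    if record.time[static_stop - 1] - record.time[0] < 0.5:
        raise ValueError("record has no usable static phase before movement")
    if record.time[stop - 1] - record.time[start] < cfg.min_movement_s:
        raise ValueError("movement phase shorter than the configured minimum")
    return slice(0, static_stop), slice(start, stop)


# ---------------------------------------------------------------------------
# axis estimators
# ---------------------------------------------------------------------------

def estimate_gravity_axis(
    static: ImuRecord, cfg: CalibrationConfig | None = None
) -> np.ndarray:
    """Lab-down direction in sensor coordinates from a static record.

    The accelerometer reads specific force (pointing up at rest), so the
    gravity axis is the negated, normalized mean accelerometer vector.
    """
    cfg = cfg or CalibrationConfig()
    # reuse the AHRS static checks (motion + magnitude)
    init_from_static(
        static, cfg.static_window_s, cfg.ahrs.static_gyro_rms_max_dps
    )
    mean_a = static.accel.mean(axis=0)
    return -mean_a / np.linalg.norm(mean_a)


def _principal_direction(M: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Leading eigenvector of a 3x3 symmetric moment matrix."""
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    total = float(vals.sum())
    ev = float(vals[0] / total) if total > 0 else 0.0
    ratio = float(vals[1] / vals[0]) if vals[0] > 0 else 1.0
    return vecs[:, 0], ev, ratio


def principal_rotation_axis(
    gyro: np.ndarray,
    cfg: CalibrationConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Principal rotation axis of a movement-phase gyroscope cloud.

    Uncentered second-moment PCA: rotation about a fixed axis makes every
    angular-velocity sample parallel or antiparallel to that axis, so the
    second moment (not the centered covariance) carries the geometry.  The
    sign is canonicalized so the net signed rotation over the first half of
    the movement is positive, matching movement templates that begin with a
    backward-tilt recovery.

    Returns (unit axis in sensor frame, explained-variance ratio).
    """
    cfg = cfg or CalibrationConfig()
    gyro = np.asarray(gyro, dtype=float)
    rms_dps = np.degrees(np.sqrt(np.mean(np.sum(gyro**2, axis=1))))
    if rms_dps < cfg.pca_min_rms_dps:
        raise ValueError(
            f"gyro rms {rms_dps:.1f} deg/s below the motion threshold; "
            "not a movement phase"
        )
    M = gyro.T @ gyro / len(gyro)
    axis, ev, ratio = _principal_direction(M)
    if ratio > cfg.eig_ambiguity_ratio:
        raise AmbiguousAxisError(
            f"top two eigenvalues within {100 * (1 - ratio):.1f}% of each "
            "other; movement is not planar enough to define a rotation axis"
        )
    half = len(gyro) // 2
    if np.sum(gyro[:half] @ axis) < 0:
        axis = -axis
    return axis, ev


def principal_acceleration_axis(
    movement: ImuRecord,
    orientation: OrientationSeries,
    cfg: CalibrationConfig | None = None,
    static_orientation: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Anterior axis from lab-frame accelerations of a walking movement.

    Accelerometer samples are rotated into the filter's lab frame, the
    gravity offset (0, 0, -1) g removed, and the first mean-centered
    principal direction computed.  Its horizontal projection is taken as the
    anterior (progression) direction, signed to point along the mean
    progression velocity (cumulative integral of the horizontal dynamic
    acceleration, positive for a walk that starts from rest), and expressed
    back in sensor coordinates via the static-phase orientation.

    Returns (unit axis in sensor frame, explained-variance ratio).
    """
    cfg = cfg or CalibrationConfig()
    if len(orientation) != len(movement.time):
        raise ValueError("orientation series must cover the movement record")
    a_lab = quat_rotate(orientation.quat, movement.accel)
    dyn = a_lab - np.array([0.0, 0.0, -1.0])
    dyn = dyn - dyn.mean(axis=0)
    M = dyn.T @ dyn / len(dyn)
    axis_lab, ev, _ratio = _principal_direction(M)
    vert = abs(axis_lab[2])
    if vert > np.cos(np.deg2rad(cfg.vertical_cone_deg)):
        raise ValueError(
            "principal acceleration direction is within "
            f"{cfg.vertical_cone_deg} deg of vertical; no anterior axis"
        )
    horiz = axis_lab.copy()
    horiz[2] = 0.0
    horiz /= np.linalg.norm(horiz)
    # sign: along the mean progression velocity accumulated from rest
    dt = 1.0 / movement.fs
    vel = np.cumsum(dyn[:, :2], axis=0) * dt
    if float(vel.mean(axis=0) @ horiz[:2]) < 0:
        horiz = -horiz
    if static_orientation is None:
        static_orientation = orientation.quat[0]
    R0 = quat_to_matrix(static_orientation)
    axis_sensor = R0.T @ horiz
    return axis_sensor / np.linalg.norm(axis_sensor), ev


# ---------------------------------------------------------------------------
# frame construction
# ---------------------------------------------------------------------------

def build_segment_frame(
    axes: FunctionalAxes,
    option: str = "gravity_aligned",
    axis_role: str = "lateral",
) -> np.ndarray:
    """Resolve (gravity, functional) axes into a sensor-to-segment rotation.

    ``axis_role`` says which segment axis the functional axis estimates:
    ``lateral`` (X, rotation-based calibrations) or ``anterior`` (Y,
    acceleration-based).  Returns the matrix whose rows are the segment
    X/Y/Z axes in sensor coordinates, i.e. ``v_segment = R @ v_sensor``.
    """
    if option not in FRAME_OPTIONS:
        raise ValueError(f"unknown frame option {option!r}")
    if axis_role not in ("lateral", "anterior"):
        raise ValueError(f"unknown axis role {axis_role!r}")
    g = axes.gravity_axis_sensor
    r = axes.functional_axis_sensor
    separation = np.degrees(np.arccos(np.clip(abs(float(g @ r)), 0.0, 1.0)))
    if separation < 15.0:
        raise ValueError(
            f"gravity and functional axes are {separation:.1f} deg from "
            "parallel (< 15 deg); frame construction is ill-conditioned"
        )

    if option == "gravity_aligned":
        z = g
        proj = r - (r @ z) * z
        n = np.linalg.norm(proj)
        axis = proj / n
        if axis_role == "lateral":
            x = axis
            y = np.cross(z, x)
        else:
            y = axis
            x = np.cross(y, z)
    else:  # functional_aligned
        if axis_role == "lateral":
            x = r
            z = g - (g @ x) * x
            z /= np.linalg.norm(z)
            y = np.cross(z, x)
        else:
            y = r
            z = g - (g @ y) * y
            z /= np.linalg.norm(z)
            x = np.cross(y, z)
    R = np.stack([x, y, z])
    return assert_rotation(R, tol=1e-9)


# ---------------------------------------------------------------------------
# full procedure
# ---------------------------------------------------------------------------

def calibrate(
    static: ImuRecord | None,
    movement: ImuRecord,
    kind: str,
    option: str = "gravity_aligned",
    axis_role: str | None = None,
    cfg: CalibrationConfig | None = None,
    phases: tuple[slice, slice] | None = None,
) -> SegmentCalibration:
    """Run one functional calibration for one sensor.

    ``static`` may be None when the movement record itself starts with a
    quiet standing phase (the generator's trials do); the phases are then
    segmented by gyro magnitude.  Dispatches to rotation-PCA for
    tilted/extension/squat and to acceleration-PCA for walking.  The default
    axis role is lateral for rotation-based and anterior for
    acceleration-based calibrations, matching the sagittal-rotation versus
    progression-acceleration physics.
    """
    cfg = cfg or CalibrationConfig()
    if kind not in ROTATION_KINDS + ("walking",):
        raise ValueError(f"unknown calibration movement kind {kind!r}")
    try:
        if phases is None:
            phases = segment_phases(movement, cfg)
        static_sl, movement_sl = phases
        if static is None:
            static = movement.slice(static_sl)
        move = movement.slice(movement_sl)

        g = estimate_gravity_axis(static, cfg)

        if kind in ROTATION_KINDS:
            role = axis_role or "lateral"
            axis, ev = principal_rotation_axis(move.gyro, cfg)
            axes = FunctionalAxes(g, axis, "rotation_pca", ev)
        else:
            role = axis_role or "anterior"
            q0 = init_from_static(
                static, cfg.static_window_s, cfg.ahrs.static_gyro_rms_max_dps
            )
            orient = estimate_orientation(movement, q0, cfg.ahrs)
            axis, ev = principal_acceleration_axis(
                movement.slice(movement_sl),
                OrientationSeries(
                    movement.time[movement_sl],
                    orient.quat[movement_sl],
                    orient.integral_error,
                ),
                cfg,
                static_orientation=q0,
            )
            axes = FunctionalAxes(g, axis, "acceleration_pca", ev)
        R = build_segment_frame(axes, option=option, axis_role=role)
    except ValueError as err:
        raise type(err)(f"[sensor {movement.sensor_id}] {err}") from err
    return SegmentCalibration(
        sensor_id=movement.sensor_id,
        R_sensor_to_segment=R,
        frame_option=option,
        movement_kind=kind,
        axes=axes,
    )


def calibrate_trial(
    records: dict[str, ImuRecord],
    kind: str,
    option: str = "gravity_aligned",
    cfg: CalibrationConfig | None = None,
) -> dict[str, SegmentCalibration]:
    """Calibrate every sensor of a trial's record set.

    The static/movement phases are segmented on the shared timeline using
    the maximum gyro magnitude across sensors: every sensor of a trial moves
    at the same time even when its own excursion is small (the squat's shank
    and foot).
    """
    cfg = cfg or CalibrationConfig()
    mags = np.stack(
        [np.degrees(np.linalg.norm(r.gyro, axis=1)) for r in records.values()]
    )
    any_record = next(iter(records.values()))
    phases = segment_phases(any_record, cfg, magnitude_dps=mags.max(axis=0))
    return {
        sid: calibrate(None, rec, kind, option=option, cfg=cfg, phases=phases)
        for sid, rec in records.items()
    }
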