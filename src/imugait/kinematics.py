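"""Segment orientations and lower-limb joint angles.

Combines AHRS sensor orientations with sensor-to-segment calibrations to
express each segment in the lab frame, then decomposes adjacent-segment
relative rotations into Cardan angles (flexion about X, abduction about Y',
axial rotation about Z''), the clinical joint-angle convention.  Pelvis
angles are computed against the lab frame itself.

Because the filter runs without a magnetometer, each sensor's lab frame has
an arbitrary heading.  The pipeline resolves this with the static upright
posture at the start of every record: all segments are assumed to face the
same direction there, so the heading (twist about lab Z) of each estimated
*segment* orientation is zeroed over the static window.  Without this step a
yaw component in the mounting misalignment would leak into the joint angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ahrs import OrientationSeries
from .calibration import SegmentCalibration
from .rotations import (
    GIMBAL_GUARD_DEG,
    cardan_series_from_matrices,
    heading_angle_rad,
    quat_to_matrix,
    rotz,
)
from .synthetic_data import JOINT_CHAIN, SEGMENT_OF_SENSOR

__all__ = [
    "JointAngleSeries",
    "segment_orientation_lab",
    "joint_angles",
    "compute_joint_angles",
    "time_normalize",
]

PLANE_COLUMNS = ("flexion_deg", "abduction_deg", "rotation_deg")


@dataclass
class JointAngleSeries:
    """Per-joint Cardan angle time series in degrees.

    ``angles`` is (N, 3): flexion, abduction, rotation.  ``gimbal_flags``
    marks samples whose middle angle is within half a degree of +/-90 deg.
    """

    joint_id: str
    time: np.ndarray
    angles: np.ndarray
    gimbal_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if np.isnan(self.angles).any():
            raise ValueError("joint angle series contains NaNs")
        if self.gimbal_flags is None:
            self.gimbal_flags = (
                np.abs(np.abs(self.angles[:, 1]) - 90.0) < GIMBAL_GUARD_DEG
            )

    def plane(self, name: str) -> np.ndarray:
        idx = {"sagittal": 0, "frontal": 1, "transverse": 2}[name]
        return self.angles[:, idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.angles, columns=list(PLANE_COLUMNS))
        df.insert(0, "time_s", self.time)
        df.insert(1, "joint", self.joint_id)
        return df


def segment_orientation_lab(
    orientation: OrientationSeries,
    calib: SegmentCalibration,
    zero_heading_window: slice | None = None,
) -> np.ndarray:
    """Per-sample lab<-segment rotation stack (N, 3, 3).

    ``R_lab<-segment = R_lab<-sensor @ R_sensor->segment^T``.  When
    ``zero_heading_window`` is given (the static standing samples), the mean
    heading of the segment over that window is removed, anchoring the
    segment frame to the lab frame at the static posture.
    """
    Rs = quat_to_matrix(orientation.quat)
    Rseg = Rs @ calib.R_sensor_to_segment.T
    if zero_heading_window is not None:
        from scipy.spatial.transform import Rotation as _Rot

        q_static = _Rot.from_matrix(
            Rseg[zero_heading_window]
        ).as_quat(scalar_first=True)
        # mean heading via circular average of the per-sample twist
        psi = heading_angle_rad(q_static)
        psi_mean = np.arctan2(np.mean(np.sin(psi)), np.mean(np.cos(psi)))
        Rseg = rotz(-np.degrees(psi_mean)) @ Rseg
    return Rseg


def joint_angles(
    proximal: np.ndarray | None,
    distal: np.ndarray,
    joint_id: str,
    time: np.ndarray,
) -> JointAngleSeries:
    """Cardan decomposition of the proximal->distal relative rotation.

    ``proximal``/``distal`` are (N, 3, 3) lab<-segment stacks; ``proximal``
    None means the lab frame (pelvis orientation).  Gimbal-proximity samples
    are flagged, not dropped.
    """
    if proximal is None:
        rel = distal
    else:
        if len(proximal) != len(distal):
            raise ValueError("proximal and distal series must share a time base")
        rel = np.einsum("nji,njk->nik", proximal, distal)
    ang = cardan_series_from_matrices(rel)
    return JointAngleSeries(joint_id, np.asarray(time, dtype=float), ang)


def compute_joint_angles(
    orientations: dict[str, OrientationSeries],
    calibrations: dict[str, SegmentCalibration],
    zero_heading_window: slice | None = None,
) -> dict[str, JointAngleSeries]:
    """Full angle set (pelvis + hips/knees/ankles) from sensor orientations.

    ``orientations`` and ``calibrations`` are keyed by sensor id.  Heading
    zeroing (see :func:`segment_orientation_lab`) defaults to the
    calibration-free static convention when a window is provided.
    """
    seg_rot: dict[str, np.ndarray] = {}
    time = None
    for sid, orient in orientations.items():
        calib = calibrations[sid]
        if calib.sensor_id != sid:
            raise ValueError(
                f"calibration for sensor {calib.sensor_id!r} applied to "
                f"record of sensor {sid!r}"
            )
        seg_rot[SEGMENT_OF_SENSOR[sid]] = segment_orientation_lab(
            orient, calib, zero_heading_window
        )
        time = orient.time
    out = {}
    for joint, (prox, dist) in JOINT_CHAIN.items():
        if dist not in seg_rot or (prox is not None and prox not in seg_rot):
            continue
        out[joint] = joint_angles(
            seg_rot[prox] if prox else None, seg_rot[dist], joint, time
        )
    return out


def time_normalize(
    series: JointAngleSeries, start: int, end: int, n_points: int = 101
) -> JointAngleSeries:
    """Resample one gait cycle onto 0-100% (1% steps, endpoints exact)."""
    n = len(series.time)
    if not (0 <= start < end < n):
        raise ValueError(f"cycle indices [{start}, {end}] out of range for {n}")
    src = np.linspace(0.0, 100.0, end - start + 1)
    dst = np.linspace(0.0, 100.0, n_points)
    seg = series.angles[start : end + 1]
    out = np.column_stack([np.interp(dst, src, seg[:, i]) for i in range(3)])
    # guard against interpolation round-off at the exact endpoints
    out[0] = seg[0]
    out[-1] = seg[-1]
    return JointAngleSeries(series.joint_id, dst, out)
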