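"""3D rotation algebra for the kinematics pipeline.

Conventions used throughout the package (stated once, here):

* Quaternions are scalar-first ``(w, x, y, z)``, unit-norm, and canonical-sign
  (``w >= 0``) at every public boundary, so each orientation has a unique
  representation.
* Rotations are passive frame maps: a quaternion or matrix labelled
  ``lab<-sensor`` maps coordinates of a vector expressed in the sensor frame to
  its coordinates in the lab frame.
* The lab frame is the right-handed triad X = medio-lateral pointing left,
  Y = anterio-posterior pointing forward, Z = vertical pointing *down*
  (left x anterior = down).
* Angles are radians internally and degrees at every public boundary.

Joint angles use the mobile-axis Cardan sequence X -> Y' -> Z''
(flexion -> abduction -> axial rotation), the clinical flexion-first
convention. The sequence is exposed as :data:`CARDAN_SEQUENCE` for users who
need a different convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation as _Rot

__all__ = [
    "CARDAN_SEQUENCE",
    "CardanAngles",
    "axis_angle",
    "cardan_from_matrix",
    "compose_quat",
    "geodesic_angle_deg",
    "heading_angle_rad",
    "matrix_from_cardan",
    "matrix_to_quat",
    "quat_conjugate",
    "quat_from_rotvec",
    "quat_multiply",
    "quat_normalize",
    "quat_rotate",
    "quat_to_matrix",
    "rotx",
    "roty",
    "rotz",
]

#: Mobile-axis Cardan sequence used for joint-angle decomposition.
CARDAN_SEQUENCE = "XYZ"

_UNIT_TOL = 1e-6
#: |abduction| within this many degrees of 90 raises the gimbal-proximity flag.
GIMBAL_GUARD_DEG = 0.5


@dataclass(frozen=True)
class CardanAngles:
    """Cardan angles in degrees for one sample.

    ``flexion_deg`` is the rotation about the (medio-lateral) X axis,
    ``abduction_deg`` about the rotated Y' axis and ``rotation_deg`` about the
    twice-rotated Z'' axis.  ``gimbal_warning`` is set when the middle angle is
    within ``GIMBAL_GUARD_DEG`` of +/-90 deg, where the outer angles become
    ill-conditioned.
    """

    flexion_deg: float
    abduction_deg: float
    rotation_deg: float
    gimbal_warning: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.flexion_deg, self.abduction_deg, self.rotation_deg]
        )


# ---------------------------------------------------------------------------
# quaternion primitives
# ---------------------------------------------------------------------------

def quat_normalize(q: np.ndarray, canonical: bool = True) -> np.ndarray:
    """Normalize quaternion(s) to unit norm; optionally enforce w >= 0."""
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero quaternion cannot be normalized")
    q = q / norm
    if canonical:
        sign = np.where(q[..., :1] < 0, -1.0, 1.0)
        q = q * sign
    return q


def _require_unit(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    err = np.abs(np.linalg.norm(q, axis=-1) - 1.0)
    if np.any(err > _UNIT_TOL):
        raise ValueError(
            f"quaternion norm deviates from 1 by {float(np.max(err)):.2e} "
            f"(tolerance {_UNIT_TOL:.0e})"
        )
    return q


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p * q (composition: apply q first, then p)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = (p[..., i] for i in range(4))
    qw, qx, qy, qz = (q[..., i] for i in range(4))
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def compose_quat(*qs: np.ndarray) -> np.ndarray:
    """Compose rotations left to right: compose_quat(a, b) applies b, then a."""
    out = np.asarray(qs[0], dtype=float)
    for q in qs[1:]:
        out = quat_multiply(out, q)
    return quat_normalize(out)


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion(s) q (source -> target coordinates)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = q[..., 1:]
    qw = q[..., :1]
    t = 2.0 * np.cross(qv, v)
    return v + qw * t + np.cross(qv, t)


def quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Quaternion for a rotation vector (axis * angle, radians)."""
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv, axis=-1, keepdims=True)
    half = 0.5 * angle
    # small-angle-safe sinc
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(angle > 1e-12, np.sin(half) / np.where(angle == 0, 1, angle), 0.5)
    return np.concatenate([np.cos(half), k * rv], axis=-1)


def axis_angle(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_deg`` about ``axis``.

    ``axis`` must be unit-norm within 1e-6.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"rotation axis must be unit-norm (got |axis|={n:.6f})")
    half = 0.5 * np.deg2rad(angle_deg)
    return quat_normalize(
        np.concatenate([[np.cos(half)], np.sin(half) * axis / n])
    )


# ---------------------------------------------------------------------------
# matrix conversions
# ---------------------------------------------------------------------------

def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Direction-cosine matrix of q (same source -> target map)."""
    q = _require_unit(q)
    return _Rot.from_quat(q, scalar_first=True).as_matrix()


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Canonical-sign scalar-first quaternion of a proper rotation matrix."""
    R = assert_rotation(np.asarray(R, dtype=float))
    q = _Rot.from_matrix(R).as_quat(scalar_first=True)
    return quat_normalize(q)


def assert_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Validate orthonormality and det=+1 of rotation matrix/matrices."""
    R = np.asarray(R, dtype=float)
    eye = np.eye(3)
    err = np.abs(np.swapaxes(R, -1, -2) @ R - eye).max()
    if err > tol:
        raise ValueError(f"matrix not orthonormal (max |R'R - I| = {err:.2e})")
    det = np.linalg.det(R)
    if np.any(np.abs(det - 1.0) > tol):
        raise ValueError("matrix is not a proper rotation (det != +1)")
    return R


def rotx(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def roty(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def rotz(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


# ---------------------------------------------------------------------------
# Cardan decomposition  (mobile axes X -> Y' -> Z'')
# ---------------------------------------------------------------------------
# R = Rx(a) @ Ry(b) @ Rz(c):
#   R[0,2] =  sin b
#   R[1,2] = -sin a cos b      R[2,2] = cos a cos b
#   R[0,1] = -cos b sin c      R[0,0] = cos b cos c

def cardan_from_matrix(R: np.ndarray) -> CardanAngles:
    """Decompose a proper rotation into mobile-axis X-Y'-Z'' Cardan angles."""
    a = cardan_series_from_matrices(R[np.newaxis])
    flex, abd, rot = (float(a[0, i]) for i in range(3))
    return CardanAngles(
        flex, abd, rot, gimbal_warning=bool(abs(abs(abd) - 90.0) < GIMBAL_GUARD_DEG)
    )


def cardan_series_from_matrices(R: np.ndarray) -> np.ndarray:
    """Vectorized X-Y'-Z'' decomposition of an (N,3,3) stack, degrees (N,3)."""
    R = assert_rotation(R)
    sb = np.clip(R[..., 0, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    a = np.arctan2(-R[..., 1, 2], R[..., 2, 2])
    c = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    return np.degrees(np.stack([a, b, c], axis=-1))


def matrix_from_cardan(
    flexion_deg: float, abduction_deg: float, rotation_deg: float
) -> np.ndarray:
    """Recompose Rx(flexion) @ Ry(abduction) @ Rz(rotation)."""
    return rotx(flexion_deg) @ roty(abduction_deg) @ rotz(rotation_deg)


# ---------------------------------------------------------------------------
# distances and heading
# ---------------------------------------------------------------------------

def geodesic_angle_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Angle (deg) of the single rotation separating two orientations."""
    Ra = np.asarray(Ra, dtype=float)
    Rb = np.asarray(Rb, dtype=float)
    if Ra.shape[-1] == 4:
        Ra = quat_to_matrix(Ra)
    if Rb.shape[-1] == 4:
        Rb = quat_to_matrix(Rb)
    tr = np.trace(Ra.T @ Rb)
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def heading_angle_rad(q: np.ndarray) -> np.ndarray:
    """Twist of q about the lab Z axis (heading/yaw), radians.

    Uses the twist-swing decomposition: the Z-twist of ``(w, x, y, z)`` is
    ``2 * atan2(z, w)``, robust near the gimbal configuration.
    """
    q = np.asarray(q, dtype=float)
    return 2.0 * np.arctan2(q[..., 3], q[..., 0])


def wrap_deg(angle: np.ndarray) -> np.ndarray:
    """Map angles (deg) to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    return wrapped
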