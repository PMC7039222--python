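"""Synthetic seven-segment lower-limb gait and IMU signal generator.

This module plays the role of the optical reference system: it produces
error-free ground-truth segment orientations and joint angles for a
seven-segment lower-body model (pelvis, both thighs, shanks and feet) and
synthesizes the tri-axial gyroscope / accelerometer records a body-worn IMU
would measure, including mounting misalignment, gyroscope bias and additive
sensor noise.

Movements covered:

* walking at three speeds (slow / self-selected / fast), built from per-joint
  per-plane Fourier waveforms whose default sagittal ranges of motion match
  typical young-adult gait (pelvis ~13 deg, hip ~50 deg, knee ~73 deg,
  ankle ~46 deg);
* the four functional calibration movements (tilted-to-stand, extension
  stand-up, squat, walking), each an upright static phase followed by a
  sagittal-plane excursion of every segment.  The squat intentionally moves
  the shank and foot through a much smaller excursion than the thigh — the
  property that degrades distal calibration accuracy.

Execution imperfection is modelled by (a) a per-repetition random rotation of
the movement plane ("wobble") and (b) smooth low-frequency parasitic
rotations about the segment's off-plane axes with an absolute angular
amplitude ("contamination").  The latter is what biases a principal-axis fit
when the commanded excursion is small.

Sign conventions: the lab Z axis points down, gravity is +9.81 m/s^2 along
+Z, and the accelerometer outputs specific force in g, so a static sensor
aligned with the lab reads (0, 0, -1) g.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as _Rot

from .rotations import assert_rotation, cardan_series_from_matrices, rotz

__all__ = [
    "SEGMENTS",
    "SENSORS",
    "JOINTS",
    "PLANES",
    "GRAVITY",
    "GaitWaveformConfig",
    "CalibrationMovementConfig",
    "SensorModel",
    "ImuRecord",
    "SyntheticTrial",
    "generate_gait_trajectory",
    "forward_kinematics",
    "simulate_imu",
    "generate_calibration_movement",
    "synthesize_trial",
]

GRAVITY = 9.81  # m/s^2, along lab +Z (down)

SEGMENTS = (
    "pelvis",
    "thigh_R", "thigh_L",
    "shank_R", "shank_L",
    "foot_R", "foot_L",
)
#: sensor ids: the pelvis sensor sits at the fifth lumbar vertebra (L5).
SENSORS = ("L5", "thigh_R", "thigh_L", "shank_R", "shank_L", "foot_R", "foot_L")
JOINTS = ("pelvis", "hip_R", "hip_L", "knee_R", "knee_L", "ankle_R", "ankle_L")
PLANES = ("sagittal", "frontal", "transverse")

SENSOR_OF_SEGMENT = dict(zip(SEGMENTS, SENSORS))
SEGMENT_OF_SENSOR = dict(zip(SENSORS, SEGMENTS))

#: joint -> (proximal segment, distal segment); pelvis is measured vs the lab.
JOINT_CHAIN = {
    "pelvis": (None, "pelvis"),
    "hip_R": ("pelvis", "thigh_R"),
    "hip_L": ("pelvis", "thigh_L"),
    "knee_R": ("thigh_R", "shank_R"),
    "knee_L": ("thigh_L", "shank_L"),
    "ankle_R": ("shank_R", "foot_R"),
    "ankle_L": ("shank_L", "foot_L"),
}

# ---------------------------------------------------------------------------
# waveform templates
# ---------------------------------------------------------------------------
# Unit gait waveforms as (harmonic, amplitude, phase) triples evaluated as
# sum a_k * cos(2 pi k phi + phase).  Each template is rescaled at run time so
# its peak-to-peak excursion over the cycle equals the configured ROM.  The
# shapes are stylized (smooth, correct dominant harmonics) rather than
# subject-specific.
_SHAPES: dict[tuple[str, str], list[tuple[int, float, float]]] = {
    ("hip", "sagittal"): [(1, 1.0, 0.25), (2, 0.12, 1.0)],
    ("hip", "frontal"): [(1, 1.0, -0.6), (2, 0.25, 0.9)],
    ("hip", "transverse"): [(1, 1.0, 1.8), (2, 0.2, -0.4)],
    ("knee", "sagittal"): [(1, 0.45, 2.4), (2, 0.55, -0.9), (3, 0.15, 0.2)],
    ("knee", "frontal"): [(1, 1.0, 0.8), (2, 0.3, -1.2)],
    ("knee", "transverse"): [(1, 1.0, -2.0), (2, 0.25, 0.5)],
    ("ankle", "sagittal"): [(1, 0.8, -2.6), (2, 0.5, 0.8)],
    ("ankle", "frontal"): [(1, 1.0, 1.4), (2, 0.35, -0.7)],
    ("ankle", "transverse"): [(1, 1.0, -0.9), (2, 0.3, 1.6)],
    ("pelvis", "sagittal"): [(2, 1.0, 0.3)],
    ("pelvis", "frontal"): [(1, 1.0, 0.5), (2, 0.3, -1.0)],
    ("pelvis", "transverse"): [(1, 1.0, -2.4)],
}

#: mean joint posture during walking (deg), added to the zero-mean waveform.
_OFFSETS = {"pelvis": 6.0, "hip": 8.0, "knee": 22.0, "ankle": 0.0}

#: default walking ROM (deg) per joint and plane; right/left values are the
#: typical side-specific gait amplitudes the package targets by default.
_DEFAULT_ROM = {
    ("pelvis", "sagittal"): 12.8, ("pelvis", "frontal"): 6.8,
    ("pelvis", "transverse"): 17.9,
    ("hip_R", "sagittal"): 50.4, ("hip_R", "frontal"): 14.0,
    ("hip_R", "transverse"): 18.4,
    ("hip_L", "sagittal"): 46.9, ("hip_L", "frontal"): 15.0,
    ("hip_L", "transverse"): 17.2,
    ("knee_R", "sagittal"): 73.3, ("knee_R", "frontal"): 11.8,
    ("knee_R", "transverse"): 18.9,
    ("knee_L", "sagittal"): 75.2, ("knee_L", "frontal"): 10.4,
    ("knee_L", "transverse"): 19.7,
    ("ankle_R", "sagittal"): 46.3, ("ankle_R", "frontal"): 18.5,
    ("ankle_R", "transverse"): 21.3,
    ("ankle_L", "sagittal"): 41.0, ("ankle_L", "frontal"): 17.4,
    ("ankle_L", "transverse"): 19.8,
}

_SPEED_PRESETS = {  # label -> (progression speed m/s, cadence strides/s)
    "slow": (0.6, 0.72),
    "selfselected": (1.0, 0.9),
    "fast": (1.5, 1.08),
}


def default_rom_table() -> dict[tuple[str, str], float]:
    """Copy of the default per-joint per-plane walking ROM targets (deg)."""
    return dict(_DEFAULT_ROM)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class GaitWaveformConfig:
    """Fourier gait-waveform configuration.

    ``rom_deg`` maps (joint, plane) to the peak-to-peak excursion of that
    angle over the gait cycle; the waveform shapes are fixed templates scaled
    to hit the configured ROM exactly on the continuous cycle.
    """

    rom_deg: dict[tuple[str, str], float] = field(default_factory=default_rom_table)
    speed: str = "selfselected"
    cadence_strides_per_s: float | None = None  # None -> speed preset
    n_strides: int = 5
    fs: float = 128.0
    static_s: float = 5.0          # upright lead-in for AHRS initialization
    ramp_strides: float = 1.0      # smooth start/stop envelope length

    def cadence(self) -> float:
        if self.cadence_strides_per_s is not None:
            return self.cadence_strides_per_s
        return _SPEED_PRESETS[self.speed][1]

    def progression_speed(self) -> float:
        return _SPEED_PRESETS[self.speed][0]


@dataclass
class CalibrationMovementConfig:
    """One functional calibration movement (static phase + sagittal excursion).

    ``excursion_deg`` gives the sagittal rotation of each segment group during
    the movement phase.  ``wobble_sd_deg`` is the standard deviation of the
    per-repetition random rotation of the whole movement plane;
    ``contamination_deg`` the rms amplitude of smooth parasitic off-plane
    rotations during execution.  Both are zero for an idealized movement.
    """

    kind: str = "tilted"
    excursion_deg: dict[str, float] = field(default_factory=dict)
    static_s: float = 5.0
    movement_s: float = 4.0
    wobble_sd_deg: float = 2.0
    contamination_deg: float = 1.0
    fs: float = 128.0
    speed: str = "selfselected"    # walking kind only
    n_strides: int = 5             # walking kind only

    _DEFAULT_EXCURSIONS = {
        # Segment sagittal excursions (deg).  The squat keeps the shank and
        # foot nearly vertical, hence their much smaller excursion.
        "tilted": {"pelvis": 45.0, "thigh": 60.0, "shank": 50.0, "foot": 45.0},
        "extension": {"pelvis": 40.0, "thigh": 70.0, "shank": 60.0, "foot": 40.0},
        "squat": {"pelvis": 30.0, "thigh": 80.0, "shank": 8.0, "foot": 10.0},
    }

    def __post_init__(self) -> None:
        if self.kind not in ("tilted", "extension", "squat", "walking"):
            raise ValueError(f"unknown calibration movement kind: {self.kind!r}")
        if self.kind != "walking" and not self.excursion_deg:
            self.excursion_deg = dict(self._DEFAULT_EXCURSIONS[self.kind])
        if self.kind == "squat":
            exc = self.excursion_deg
            if not (exc["shank"] < exc["thigh"] and exc["foot"] < exc["thigh"]):
                raise ValueError(
                    "squat calibration requires shank and foot excursions "
                    "smaller than the thigh excursion"
                )


@dataclass
class SensorModel:
    """IMU error model: mounting misalignment, gyro bias, additive noise.

    ``misalignment`` maps sensor id -> sensor-to-segment rotation matrix (the
    true mounting orientation the calibration must recover).  Noise standard
    deviations are per axis; ``gyro_bias`` is a constant per-sensor offset.
    """

    misalignment: dict[str, np.ndarray] = field(default_factory=dict)
    gyro_noise_sd: float = 0.005      # rad/s
    gyro_bias: dict[str, np.ndarray] = field(default_factory=dict)
    accel_noise_sd: float = 0.02      # g
    fs: float = 128.0

    def __post_init__(self) -> None:
        if self.gyro_noise_sd < 0 or self.accel_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.fs <= 0:
            raise ValueError("sample rate must be > 0")
        for sid, R in self.misalignment.items():
            assert_rotation(np.asarray(R, dtype=float))

    def misalignment_of(self, sensor_id: str) -> np.ndarray:
        return np.asarray(self.misalignment.get(sensor_id, np.eye(3)), dtype=float)

    def bias_of(self, sensor_id: str) -> np.ndarray:
        return np.asarray(self.gyro_bias.get(sensor_id, np.zeros(3)), dtype=float)

    @staticmethod
    def random(
        rng: np.random.Generator,
        max_misalignment_deg: float = 20.0,
        gyro_noise_sd: float = 0.005,
        gyro_bias_sd: float = 0.003,
        accel_noise_sd: float = 0.02,
        fs: float = 128.0,
    ) -> "SensorModel":
        """Draw a sensor model with random mounting errors and biases."""
        mis, bias = {}, {}
        for sid in SENSORS:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(0.0, np.deg2rad(max_misalignment_deg))
            mis[sid] = _Rot.from_rotvec(ang * axis).as_matrix()
            bias[sid] = rng.normal(0.0, gyro_bias_sd, size=3)
        return SensorModel(
            misalignment=mis,
            gyro_noise_sd=gyro_noise_sd,
            gyro_bias=bias,
            accel_noise_sd=accel_noise_sd,
            fs=fs,
        )


@dataclass
class ImuRecord:
    """Synchronized gyro + accelerometer samples for one sensor.

    ``gyro`` is (N, 3) in rad/s, ``accel`` (N, 3) specific force in g, both
    in the sensor frame; ``time`` is seconds, uniformly sampled.
    """

    time: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    sensor_id: str

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        n = len(self.time)
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise ValueError("gyro and accel must be (N, 3) matching time")
        if not (np.isfinite(self.gyro).all() and np.isfinite(self.accel).all()):
            raise ValueError("IMU record contains non-finite samples")
        if n > 1:
            dt = np.diff(self.time)
            if np.ptp(dt) > 1e-6 * dt.mean():
                raise ValueError("IMU record must be uniformly sampled")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def slice(self, sl: slice) -> "ImuRecord":
        return ImuRecord(self.time[sl], self.gyro[sl], self.accel[sl], self.sensor_id)

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "time_s": self.time,
                "gyro_x": self.gyro[:, 0], "gyro_y": self.gyro[:, 1],
                "gyro_z": self.gyro[:, 2],
                "accel_x": self.accel[:, 0], "accel_y": self.accel[:, 1],
                "accel_z": self.accel[:, 2],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sensor_id: str) -> "ImuRecord":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(),
            df[["accel_x", "accel_y", "accel_z"]].to_numpy(),
            sensor_id,
        )


@dataclass
class SyntheticTrial:
    """Ground truth kinematics plus the simulated IMU records encoding them."""

    time: np.ndarray
    fs: float
    segment_rot: dict[str, np.ndarray]      # segment -> (N,3,3) lab<-segment
    sensor_pos: dict[str, np.ndarray]       # sensor -> (N,3) lab position, m
    joint_angles: dict[str, np.ndarray]     # joint -> (N,3) deg (flex, abd, rot)
    static_slice: slice
    movement_slice: slice
    stride_bounds: list[tuple[int, int]] = field(default_factory=list)
    records: dict[str, ImuRecord] = field(default_factory=dict)
    sensor_model: SensorModel | None = None
    seed: int | None = None
    kind: str = "walking"

    @property
    def n_samples(self) -> int:
        return len(self.time)

    # -- HDF5 round trip ---------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["fs"] = self.fs
            f.attrs["kind"] = self.kind
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["static_slice"] = [self.static_slice.start or 0,
                                       self.static_slice.stop]
            f.attrs["movement_slice"] = [self.movement_slice.start or 0,
                                         self.movement_slice.stop]
            f.create_dataset("time", data=self.time)
            if self.stride_bounds:
                f.create_dataset("stride_bounds", data=np.asarray(self.stride_bounds))
            for name, grp_src in (
                ("segment_rot", self.segment_rot),
                ("sensor_pos", self.sensor_pos),
                ("joint_angles", self.joint_angles),
            ):
                g = f.create_group(name)
                for k, v in grp_src.items():
                    g.create_dataset(k, data=v)
            g = f.create_group("records")
            for sid, rec in self.records.items():
                sg = g.create_group(sid)
                sg.create_dataset("gyro", data=rec.gyro)
                sg.create_dataset("accel", data=rec.accel)
            if self.sensor_model is not None:
                sm = self.sensor_model
                meta = {
                    "gyro_noise_sd": sm.gyro_noise_sd,
                    "accel_noise_sd": sm.accel_noise_sd,
                    "fs": sm.fs,
                    "misalignment": {k: np.asarray(v).tolist()
                                     for k, v in sm.misalignment.items()},
                    "gyro_bias": {k: np.asarray(v).tolist()
                                  for k, v in sm.gyro_bias.items()},
                }
                f.attrs["sensor_model"] = json.dumps(meta)

    @classmethod
    def from_hdf5(cls, path) -> "SyntheticTrial":
        with h5py.File(path, "r") as f:
            time = f["time"][()]
            seg = {k: v[()] for k, v in f["segment_rot"].items()}
            pos = {k: v[()] for k, v in f["sensor_pos"].items()}
            ja = {k: v[()] for k, v in f["joint_angles"].items()}
            s0, s1 = f.attrs["static_slice"]
            m0, m1 = f.attrs["movement_slice"]
            fs = float(f.attrs["fs"])
            records = {}
            for sid, g in f["records"].items():
                records[sid] = ImuRecord(time, g["gyro"][()], g["accel"][()], sid)
            model = None
            if "sensor_model" in f.attrs:
                meta = json.loads(f.attrs["sensor_model"])
                model = SensorModel(
                    misalignment={k: np.asarray(v)
                                  for k, v in meta["misalignment"].items()},
                    gyro_noise_sd=meta["gyro_noise_sd"],
                    gyro_bias={k: np.asarray(v)
                               for k, v in meta["gyro_bias"].items()},
                    accel_noise_sd=meta["accel_noise_sd"],
                    fs=meta["fs"],
                )
            sb = [tuple(x) for x in f["stride_bounds"][()]] \
                if "stride_bounds" in f else []
            seed = int(f.attrs["seed"])
            return cls(
                time=time, fs=fs, segment_rot=seg, sensor_pos=pos,
                joint_angles=ja, static_slice=slice(int(s0), int(s1)),
                movement_slice=slice(int(m0), int(m1)), stride_bounds=sb,
                records=records, sensor_model=model,
                seed=None if seed < 0 else seed,
                kind=str(f.attrs["kind"]),
            )


# ---------------------------------------------------------------------------
# gait trajectory
# ---------------------------------------------------------------------------

def _unit_shape(template, phi: np.ndarray) -> np.ndarray:
    """Evaluate a harmonic template, normalized to peak-to-peak 1, mean 0."""
    dense = np.linspace(0.0, 1.0, 4001)
    ref = np.zeros_like(dense)
    for k, amp, ph in template:
        ref += amp * np.cos(2 * np.pi * k * dense + ph)
    scale = np.ptp(ref)
    offset = 0.5 * (ref.max() + ref.min())
    out = np.zeros_like(phi, dtype=float)
    for k, amp, ph in template:
        out += amp * np.cos(2 * np.pi * k * phi + ph)
    return (out - offset) / scale


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_gait_trajectory(
    cfg: GaitWaveformConfig, seed: int | None = None
) -> dict:
    """Generate ground-truth joint angle series for a walking movement.

    Returns a dict with ``time``, ``phi`` (gait-cycle phase, strides),
    ``angles`` (joint -> (N,3) degrees), ``envelope``, ``static_slice``,
    ``movement_slice`` and ``stride_bounds``.  The movement ramps in and out
    smoothly over ``ramp_strides`` so the record starts and ends at the
    upright static posture, with zero velocity.  Deterministic; ``seed`` is
    accepted for interface symmetry and reserved for stride-jitter extensions.
    """
    cadence = cfg.cadence()
    if cadence <= 0:
        raise ValueError("cadence must be positive")
    if cfg.n_strides < 1:
        raise ValueError("need at least one stride")
    fs = cfg.fs
    walk_s = cfg.n_strides / cadence
    n_static = int(round(cfg.static_s * fs))
    n_walk = int(round(walk_s * fs))
    n = n_static + n_walk
    time = np.arange(n) / fs

    t_walk = time[n_static:] - time[n_static]
    phi = cadence * t_walk  # strides since movement start
    # envelope: 0 -> 1 over the first ramp_strides, back to 0 over the last
    ramp = max(cfg.ramp_strides, 1e-6)
    env = _smoothstep(phi / ramp) * _smoothstep((cfg.n_strides - phi) / ramp)

    plane_col = {"sagittal": 0, "frontal": 1, "transverse": 2}
    angles: dict[str, np.ndarray] = {}
    for joint in JOINTS:
        base = joint.split("_")[0]
        side = joint.split("_")[1] if "_" in joint else None
        a = np.zeros((n, 3))
        # left leg is half a cycle out of phase; frontal/transverse mirrored
        ph = phi + (0.5 if side == "L" else 0.0)
        for plane, col in plane_col.items():
            rom = cfg.rom_deg.get((joint, plane), 0.0)
            shape = _unit_shape(_SHAPES[(base, plane)], ph)
            if side == "L" and plane in ("frontal", "transverse"):
                shape = -shape
            osc = rom * shape
            if plane == "sagittal":
                osc = osc + _OFFSETS[base]
            a[n_static:, col] = env * osc
        angles[joint] = a

    stride_bounds = []
    for k in range(cfg.n_strides):
        i0 = n_static + int(round(k / cadence * fs))
        i1 = n_static + int(round((k + 1) / cadence * fs))
        stride_bounds.append((i0, min(i1, n - 1)))

    full_phi = np.zeros(n)
    full_phi[n_static:] = phi
    return {
        "time": time,
        "phi": full_phi,
        "angles": angles,
        "envelope": env,
        "static_slice": slice(0, n_static),
        "movement_slice": slice(n_static, n),
        "stride_bounds": stride_bounds,
        "cfg": cfg,
    }


def continuous_plane_rom(
    cfg: GaitWaveformConfig, joint: str, plane: str, n_dense: int = 4001
) -> float:
    """Peak-to-peak excursion of one angle over the continuous gait cycle.

    Evaluates the configured waveform on a dense phase grid, so the value is
    the amplitude-implied ROM independent of the sampling rate.
    """
    base = joint.split("_")[0]
    phi = np.linspace(0.0, 1.0, n_dense)
    rom = cfg.rom_deg.get((joint, plane), 0.0)
    return float(np.ptp(rom * _unit_shape(_SHAPES[(base, plane)], phi)))


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

#: sensor mounting points in segment coordinates (m); lab Z points down.
_SENSOR_OFFSET = {
    "L5": np.array([0.0, -0.10, -0.15]),
    "thigh_R": np.array([0.0, 0.05, 0.20]),
    "thigh_L": np.array([0.0, 0.05, 0.20]),
    "shank_R": np.array([0.0, 0.04, 0.20]),
    "shank_L": np.array([0.0, 0.04, 0.20]),
    "foot_R": np.array([0.0, 0.08, 0.03]),
    "foot_L": np.array([0.0, 0.08, 0.03]),
}

_HIP_OFFSET = {"R": np.array([-0.09, 0.0, 0.0]), "L": np.array([0.09, 0.0, 0.0])}


@dataclass
class ChainConfig:
    """Segment geometry for linear-acceleration synthesis (configuration)."""

    thigh_length: float = 0.40
    shank_length: float = 0.40


def _cardan_matrices(angles_deg: np.ndarray) -> np.ndarray:
    """(N,3) Cardan angles (deg) -> (N,3,3) Rx @ Ry' @ Rz'' stack."""
    a = np.deg2rad(angles_deg)
    # intrinsic XYZ == extrinsic xyz reversed; use scipy for the stack
    return _Rot.from_euler("XYZ", a).as_matrix()


def forward_kinematics(
    joint_angles: dict[str, np.ndarray],
    chain: ChainConfig = ChainConfig(),
    pelvis_pos: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Propagate joint angles down the lab->pelvis->thigh->shank->foot chain.

    Returns ``(segment_rot, sensor_pos)``: per-segment lab<-segment rotation
    stacks and per-sensor lab positions (for linear-acceleration synthesis).
    ``pelvis_pos`` is the (N,3) pelvis origin trajectory (defaults to the
    origin, i.e. treadmill-like walking in place).
    """
    n = {len(v) for v in joint_angles.values()}
    if len(n) != 1:
        raise ValueError("all joint angle series must share one time base")
    n = n.pop()
    if pelvis_pos is None:
        pelvis_pos = np.zeros((n, 3))
    if len(pelvis_pos) != n:
        raise ValueError("pelvis trajectory length mismatch")

    R = {}
    R["pelvis"] = _cardan_matrices(joint_angles["pelvis"])
    for side in ("R", "L"):
        R[f"thigh_{side}"] = R["pelvis"] @ _cardan_matrices(joint_angles[f"hip_{side}"])
        R[f"shank_{side}"] = (
            R[f"thigh_{side}"] @ _cardan_matrices(joint_angles[f"knee_{side}"])
        )
        R[f"foot_{side}"] = (
            R[f"shank_{side}"] @ _cardan_matrices(joint_angles[f"ankle_{side}"])
        )

    pos = {}
    pos["L5"] = pelvis_pos + np.einsum("nij,j->ni", R["pelvis"], _SENSOR_OFFSET["L5"])
    for side in ("R", "L"):
        hip = pelvis_pos + np.einsum(
            "nij,j->ni", R["pelvis"], _HIP_OFFSET[side]
        )
        pos[f"thigh_{side}"] = hip + np.einsum(
            "nij,j->ni", R[f"thigh_{side}"], _SENSOR_OFFSET[f"thigh_{side}"]
        )
        knee = hip + np.einsum(
            "nij,j->ni", R[f"thigh_{side}"],
            np.array([0.0, 0.0, chain.thigh_length]),
        )
        pos[f"shank_{side}"] = knee + np.einsum(
            "nij,j->ni", R[f"shank_{side}"], _SENSOR_OFFSET[f"shank_{side}"]
        )
        ankle = knee + np.einsum(
            "nij,j->ni", R[f"shank_{side}"],
            np.array([0.0, 0.0, chain.shank_length]),
        )
        pos[f"foot_{side}"] = ankle + np.einsum(
            "nij,j->ni", R[f"foot_{side}"], _SENSOR_OFFSET[f"foot_{side}"]
        )
    return R, pos


def _pelvis_trajectory(traj: dict) -> np.ndarray:
    """Pelvis origin for a walking trial: forward progression + oscillations.

    Progression along lab +Y at the configured speed, modulated within the
    stride, plus a small vertical bob at twice the stride frequency; all
    scaled by the movement envelope so the record starts/ends at rest.
    """
    cfg: GaitWaveformConfig = traj["cfg"]
    time = traj["time"]
    n_static = traj["static_slice"].stop
    phi = traj["phi"]
    env = np.zeros(len(time))
    env[n_static:] = traj["envelope"]
    v0 = cfg.progression_speed()
    # forward velocity with intra-stride modulation (two steps per stride)
    vy = env * v0 * (1.0 + 0.35 * np.sin(4 * np.pi * phi))
    dt = 1.0 / cfg.fs
    y = np.cumsum(vy) * dt
    z = env * (-0.015) * np.cos(2 * np.pi * 2 * phi)   # vertical bob, m
    x = env * 0.01 * np.sin(2 * np.pi * phi)           # lateral sway, m
    return np.stack([x, y, z], axis=1)


# ---------------------------------------------------------------------------
# differentiation and IMU synthesis
# ---------------------------------------------------------------------------

def angular_velocity_body(Rs: np.ndarray, fs: float) -> np.ndarray:
    """Body-frame angular velocity (rad/s) of a lab<-body rotation series.

    Central differences on the orientation manifold:
    ``omega_k = rotvec(R_{k-1}^T R_{k+1}) / (2 dt)``, with one-sided
    differences at the endpoints.  Second-order accurate estimate of the
    instantaneous rate; used for analysis.
    """
    rot = _Rot.from_matrix(Rs)
    n = len(Rs)
    dt = 1.0 / fs
    omega = np.zeros((n, 3))
    if n >= 3:
        d = rot[:-2].inv() * rot[2:]
        omega[1:-1] = d.as_rotvec() / (2 * dt)
    if n >= 2:
        omega[0] = (rot[0].inv() * rot[1]).as_rotvec() / dt
        omega[-1] = (rot[-2].inv() * rot[-1]).as_rotvec() / dt
    return omega


def angular_rates_interval(Rs: np.ndarray, fs: float) -> np.ndarray:
    """Per-sample interval-average body rates (rad/s) of a rotation series.

    ``omega_k = rotvec(R_{k-1}^T R_k) * fs`` — the mean angular velocity over
    the sampling interval ending at sample k (``omega_0 = omega_1``).  This
    is the quantity a rate gyro with internal integrate-and-decimate output
    reports, and it makes the per-step quaternion-exponential update an
    exact inverse of the synthesis for noise-free signals.
    """
    rot = _Rot.from_matrix(Rs)
    n = len(Rs)
    omega = np.zeros((n, 3))
    if n >= 2:
        omega[1:] = (rot[:-1].inv() * rot[1:]).as_rotvec() * fs
        omega[0] = omega[1]
    return omega


def _second_derivative(p: np.ndarray, fs: float) -> np.ndarray:
    """Second time derivative by central differences, clamped endpoints."""
    a = np.zeros_like(p)
    dt2 = (1.0 / fs) ** 2
    a[1:-1] = (p[2:] - 2 * p[1:-1] + p[:-2]) / dt2
    a[0] = a[1]
    a[-1] = a[-2]
    return a


def simulate_imu(
    trial: SyntheticTrial,
    sensor_model: SensorModel,
    seed: int | None = None,
) -> dict[str, ImuRecord]:
    """Synthesize one ImuRecord per sensor from ground-truth kinematics.

    For each sensor: the true sensor orientation is
    ``R_lab<-sensor = R_lab<-segment @ R_mis`` (``R_mis`` maps sensor to
    segment coordinates); the gyroscope reads the body rates of that series
    plus bias and white noise; the accelerometer reads the specific force
    ``R_lab<-sensor^T (a_lab - g_lab) / 9.81`` plus white noise, with
    ``g_lab = (0, 0, +9.81)`` m/s^2 (lab Z down).
    """
    if abs(sensor_model.fs - trial.fs) > 1e-9:
        raise ValueError(
            f"sensor model rate {sensor_model.fs} Hz does not match trial "
            f"rate {trial.fs} Hz"
        )
    rng = np.random.default_rng(seed)
    g_lab = np.array([0.0, 0.0, GRAVITY])
    records = {}
    for sensor_id in SENSORS:
        segment = SEGMENT_OF_SENSOR[sensor_id]
        R_mis = sensor_model.misalignment_of(sensor_id)
        R_sensor = trial.segment_rot[segment] @ R_mis
        omega = angular_rates_interval(R_sensor, trial.fs)
        a_lab = _second_derivative(trial.sensor_pos[sensor_id], trial.fs)
        specific = np.einsum("nji,nj->ni", R_sensor, (a_lab - g_lab) / GRAVITY)
        gyro = omega + sensor_model.bias_of(sensor_id)
        if sensor_model.gyro_noise_sd > 0:
            gyro = gyro + rng.normal(0, sensor_model.gyro_noise_sd, omega.shape)
        accel = specific
        if sensor_model.accel_noise_sd > 0:
            accel = accel + rng.normal(0, sensor_model.accel_noise_sd, accel.shape)
        records[sensor_id] = ImuRecord(trial.time, gyro, accel, sensor_id)
    return records


# ---------------------------------------------------------------------------
# calibration movements
# ---------------------------------------------------------------------------

def _parasitic_angles(
    rng: np.random.Generator, t01: np.ndarray, rms_deg: float, n_harm: int = 3
) -> np.ndarray:
    """Smooth zero-boundary parasitic angle curve with given rms (deg)."""
    if rms_deg <= 0:
        return np.zeros_like(t01)
    out = np.zeros_like(t01)
    for k in range(1, n_harm + 1):
        out += rng.normal() * np.sin(np.pi * k * t01)
    r = np.sqrt(np.mean(out**2))
    if r < 1e-12:
        return np.zeros_like(t01)
    return out * (rms_deg / r)


def _segments_to_trial(
    time: np.ndarray,
    fs: float,
    segment_rot: dict[str, np.ndarray],
    static_slice: slice,
    movement_slice: slice,
    kind: str,
    seed: int | None,
    stride_bounds=None,
) -> SyntheticTrial:
    """Assemble a trial: joint angles derived from the segment orientations."""
    joint_angles = {}
    for joint, (prox, dist) in JOINT_CHAIN.items():
        Rd = segment_rot[dist]
        if prox is None:
            rel = Rd
        else:
            rel = np.einsum("nji,njk->nik", segment_rot[prox], Rd)
        joint_angles[joint] = cardan_series_from_matrices(rel)
    # sensor positions from the chain (origins at rest for non-walking trials)
    _, pos = forward_kinematics(joint_angles)
    return SyntheticTrial(
        time=time, fs=fs, segment_rot=segment_rot, sensor_pos=pos,
        joint_angles=joint_angles, static_slice=static_slice,
        movement_slice=movement_slice, stride_bounds=stride_bounds or [],
        kind=kind, seed=seed,
    )


def generate_calibration_movement(
    cfg: CalibrationMovementConfig, seed: int | None = None
) -> SyntheticTrial:
    """Ground-truth kinematics for one functional calibration repetition.

    The trial is an upright static phase (zero angular velocity) followed by
    a movement phase in which every segment rotates about its medio-lateral
    (X) axis following a smooth raised-cosine excursion profile.  Execution
    imperfection: a per-repetition random rotation of the movement plane
    (``wobble_sd_deg``) and smooth parasitic off-plane rotations
    (``contamination_deg``); both seeded.
    """
    if cfg.kind == "walking":
        # execution variability for a walking calibration: per-repetition
        # deviation of the walking direction (wobble, deg about vertical)
        # and a small waveform amplitude jitter (2% per deg contamination)
        rng = np.random.default_rng(seed)
        rom = default_rom_table()
        if cfg.contamination_deg > 0:
            rel = 0.02 * cfg.contamination_deg
            rom = {k: v * (1.0 + rng.normal(0.0, rel)) for k, v in rom.items()}
        gcfg = GaitWaveformConfig(
            rom_deg=rom, speed=cfg.speed, n_strides=cfg.n_strides,
            static_s=cfg.static_s, fs=cfg.fs,
        )
        trial = synthesize_walking_kinematics(gcfg, seed=seed)
        if cfg.wobble_sd_deg > 0:
            # the walking path deviates from the segments' anterior axis by a
            # small per-repetition angle (the subject drifts off the line
            # rather than turning): rotate the trajectory, not the body, so
            # the progression direction no longer matches segment anterior
            Rz_dev = rotz(float(rng.normal(0.0, cfg.wobble_sd_deg)))
            trial.sensor_pos = {
                k: np.einsum("ij,nj->ni", Rz_dev, v)
                for k, v in trial.sensor_pos.items()
            }
        trial.kind = "walking"
        return trial

    rng = np.random.default_rng(seed)
    fs = cfg.fs
    n_static = int(round(cfg.static_s * fs))
    n_move = int(round(cfg.movement_s * fs))
    n = n_static + n_move
    time = np.arange(n) / fs
    t01 = (time[n_static:] - time[n_static]) / cfg.movement_s  # in [0, 1)

    group_of = {
        "pelvis": "pelvis",
        "thigh_R": "thigh", "thigh_L": "thigh",
        "shank_R": "shank", "shank_L": "shank",
        "foot_R": "foot", "foot_L": "foot",
    }
    segment_rot = {}
    for seg in SEGMENTS:
        exc = cfg.excursion_deg[group_of[seg]]
        theta = np.zeros(n)
        theta[n_static:] = exc * 0.5 * (1.0 - np.cos(2 * np.pi * t01))
        p_y = np.zeros(n)
        p_z = np.zeros(n)
        p_y[n_static:] = _parasitic_angles(rng, t01, cfg.contamination_deg)
        p_z[n_static:] = _parasitic_angles(rng, t01, cfg.contamination_deg)
        # per-repetition wobble: the subject executes the excursion about a
        # slightly rotated axis, starting from the same upright posture, so
        # the series stays continuous at the static/movement boundary
        axis = np.array([1.0, 0.0, 0.0])
        if cfg.wobble_sd_deg > 0:
            w_axis = rng.normal(size=3)
            w_axis /= np.linalg.norm(w_axis)
            w_ang = rng.normal(0.0, np.deg2rad(cfg.wobble_sd_deg))
            axis = _Rot.from_rotvec(w_ang * w_axis).as_matrix() @ axis
        main = _Rot.from_rotvec(np.deg2rad(theta)[:, None] * axis)
        parasitic = _Rot.from_euler(
            "YZ", np.stack([np.deg2rad(p_y), np.deg2rad(p_z)], axis=1)
        )
        segment_rot[seg] = (main * parasitic).as_matrix()
    return _segments_to_trial(
        time, fs, segment_rot, slice(0, n_static), slice(n_static, n),
        cfg.kind, seed,
    )


def synthesize_walking_kinematics(
    cfg: GaitWaveformConfig, seed: int | None = None
) -> SyntheticTrial:
    """Walking trial kinematics: gait waveforms + chain + pelvis progression."""
    traj = generate_gait_trajectory(cfg, seed=seed)
    pelvis_pos = _pelvis_trajectory(traj)
    segment_rot, sensor_pos = forward_kinematics(
        traj["angles"], pelvis_pos=pelvis_pos
    )
    # store angles re-derived from the orientations (consistency by
    # construction; equals the generated waveforms to numerical precision)
    joint_angles = {}
    for joint, (prox, dist) in JOINT_CHAIN.items():
        Rd = segment_rot[dist]
        rel = Rd if prox is None else np.einsum(
            "nji,njk->nik", segment_rot[prox], Rd
        )
        joint_angles[joint] = cardan_series_from_matrices(rel)
    return SyntheticTrial(
        time=traj["time"], fs=cfg.fs, segment_rot=segment_rot,
        sensor_pos=sensor_pos, joint_angles=joint_angles,
        static_slice=traj["static_slice"], movement_slice=traj["movement_slice"],
        stride_bounds=traj["stride_bounds"], kind="walking", seed=seed,
    )


def synthesize_trial(
    movement: GaitWaveformConfig | CalibrationMovementConfig,
    sensor_model: SensorModel | None = None,
    seed: int | None = None,
) -> SyntheticTrial:
    """Generate kinematics and simulate IMU records in one call.

    ``seed`` drives both the movement execution noise and the sensor noise
    (via independent child seeds), so trials are bit-reproducible.
    """
    ss = np.random.SeedSequence(seed)
    kin_seed, imu_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    if isinstance(movement, CalibrationMovementConfig):
        trial = generate_calibration_movement(movement, seed=kin_seed)
    else:
        trial = synthesize_walking_kinematics(movement, seed=kin_seed)
    if sensor_model is None:
        sensor_model = SensorModel(fs=trial.fs)
    trial.sensor_model = sensor_model
    trial.records = simulate_imu(trial, sensor_model, seed=imu_seed)
    trial.seed = seed
    return trial
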