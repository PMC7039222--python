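# Methods

This note documents the models, conventions, numerical choices and known
limitations of `imugait`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Frames, conventions, units

All frames are right-handed. The lab frame is X medio-lateral pointing
left, Y anterior, Z vertical pointing **down** (left × anterior = down), so
gravity is +9.81 m/s² along +Z and a static accelerometer reads specific
force (0, 0, −1) g. Quaternions are scalar-first, unit-norm and
canonical-sign (w ≥ 0) at public boundaries, and are passive frame maps: a
`lab←sensor` quaternion maps sensor-frame coordinates to lab-frame
coordinates. Angles are degrees at every public boundary, radians inside.

Joint angles use the mobile-axis Cardan sequence X → Y′ → Z″
(flexion → abduction → axial rotation), the clinical flexion-first
convention; the source names the axis-to-motion assignment but no
decomposition order, so the order here is a documented convention exposed as
`rotations.CARDAN_SEQUENCE`. Samples whose middle angle comes within 0.5°
of ±90° carry a gimbal-proximity flag; they are flagged, never dropped.

## Synthetic gait and IMU model

The generator is the package's reference system: it produces ground-truth
segment orientations/joint angles and the IMU signals that encode them.

**Walking.** Per-joint per-plane harmonic templates (1–3 harmonics with
gait-appropriate dominant frequencies: e.g. one cycle/stride for hip
flexion, two for pelvic tilt) are rescaled so the continuous-cycle
peak-to-peak excursion equals the configured ROM exactly. Default ROMs are
typical young-adult walking amplitudes (sagittal ≈ 12.8° pelvis, 50.4°/46.9°
hip R/L, 73.3°/75.2° knee, 46.3°/41.0° ankle, with matching frontal and
transverse values); speed presets are slow/self-selected/fast = 0.6/1.0/1.5
m/s at 0.72/0.9/1.08 strides/s. Every trial starts with a 5 s upright
static phase, and the movement ramps in/out over one stride so records begin
and end at rest. The pelvis translates forward with intra-stride speed
modulation (±35%), a 1.5 cm vertical bob at two cycles/stride and a 1 cm
lateral sway; distal sensor positions follow the chain geometry (thigh and
shank lengths 0.40 m — configuration, not measured fact), giving the
walking calibration physically plausible acceleration directions.

**Calibration movements.** Tilted-to-stand, extension stand-up and squat
are modelled as a static phase followed by a raised-cosine sagittal
excursion of each segment group; defaults (deg): tilted 45/60/50/45 and
extension 40/70/60/40 for pelvis/thigh/shank/foot, squat 30/80/**8**/**10**
— the squat's small shank and foot excursions are the property under study.
Walking calibrations reuse the gait generator.

**Execution noise.** Two seeded, per-repetition components:

* *wobble* (default sd 2°): the subject executes the excursion about a
  slightly rotated axis — a random small rotation applied to the movement
  axis itself, so the orientation series stays continuous at the
  static/movement boundary;
* *off-plane contamination* (default 1° rms): smooth low-frequency parasitic
  rotations about the segment's other two axes (sums of 1–3 half-sine
  harmonics with random weights). Because these share the movement's
  frequency band, they correlate with the main profile in any finite record
  and bias a principal-axis fit by roughly (contamination rate)/(excursion
  rate) — the amplitude-to-noise mechanism that makes the squat degrade
  distal calibrations. Isotropic white gyro noise would *not* produce this
  bias (it inflates all eigenvalues equally), which is why contamination is
  modelled as structured movement, not sensor noise.

For walking calibrations the same two knobs map to path deviation (the
trajectory, not the body, is rotated about vertical by a wobble-sd draw, so
the progression direction no longer matches the segments' anterior axes)
and a 2%-per-degree-of-contamination waveform amplitude jitter. The 1°
contamination default was set so that the default study conditions yield
well-posed squat calibrations (at 2° the 15° ill-conditioning guard
occasionally rejects the squat's foot axis outright); both values are
configuration for sensitivity studies.

**Sensor model.** Per-sensor mounting misalignment (the rotation the
calibration must recover), constant gyro bias (default sd 0.003 rad/s ≈
0.17°/s per axis), white gyro noise (0.005 rad/s) and white accelerometer
noise (0.02 g), all at 128 Hz.

**Gyro encoding.** Synthetic gyro samples are interval-average body rates,
`ω_k = rotvec(R_{k−1}ᵀ R_k)·fs` — the quantity a MEMS gyro with internal
integrate-and-decimate output reports. This makes the per-sample quaternion
exponential an exact inverse of the synthesis: the noise-free
differentiate-then-integrate round trip closes to ~1e-6° over 20 s, so
integration error never contaminates drift measurements. Instantaneous
central-difference rates remain available (`angular_velocity_body`) for
analysis. Linear accelerations are second central differences of sensor
positions.

## Attitude filter

A Mahony-type complementary filter without magnetometer. Error term
`e = â × v̂` (measured specific-force direction × predicted up direction);
corrected rate `ω + kp·e + ki·∫e`; quaternion advanced by the exponential of
one sample per step and renormalized. Accelerometer magnitudes below 0.01 g
skip the correction (free-fall guard). Initialization maps the mean static
accelerometer direction onto lab-up by the shortest rotation, leaving the
heading at zero; windows with gyro rms above 2°/s or mean |accel| off 1 g by
more than 0.1 g are rejected as non-static.

Default gains `kp = 0.5 s⁻¹`, `ki = 0`: a ~2 s attitude time constant at
128 Hz, chosen so a 0.5°/s gyro bias settles to ≈ bias/kp = 1° of tilt
error while ~2 Hz walking-acceleration disturbance is attenuated to a few
percent. Smaller `kp` tracks noise-free records more closely (≤ 1° rms at
`kp = 0.1` on simulated walking); larger `kp` trusts the accelerometer more
than gait dynamics warrant. Heading is unobservable by construction; all
cross-sensor heading reconciliation happens downstream.

## Calibration

* Gravity axis: −normalize(mean static accel) — lab-down in sensor
  coordinates.
* Principal rotation axis: leading eigenvector of the *uncentered* second
  moment of the movement-phase gyro cloud (rotation about a fixed axis makes
  ω parallel/antiparallel to it; centering would distort that geometry).
  Records whose gyro rms is below 2°/s are rejected as static; if the top
  two eigenvalues are within 5% the movement is not planar enough and an
  `AmbiguousAxisError` is raised. Sign: the signed net rotation over the
  first half of the movement is made positive, matching templates that begin
  with a backward-tilt recovery.
* Principal acceleration axis (walking): accelerations are rotated to the
  filter's lab frame, the gravity offset removed, and the first
  *mean-centered* principal direction taken (gravity subtraction is a
  package decision; the alternative leaves a constant the centering removes
  anyway). Its horizontal projection is the anterior direction — directions
  within 10° of vertical are rejected — signed along the mean progression
  velocity (cumulative integral of horizontal dynamic acceleration; positive
  for a walk starting from rest) and expressed in sensor coordinates through
  the static-phase orientation. The axis is assigned the *anterior* role,
  rotation-PCA axes the *lateral* role.
* Frame construction: `gravity_aligned` sets segment Z = g and takes the
  functional axis' component orthogonal to g; `functional_aligned` keeps the
  functional axis exact and takes the orthogonal axis closest to g as
  vertical; the third axis completes the right-handed triad. Axis pairs
  within 15° of parallel are rejected as ill-conditioned. When g ⊥ r the two
  options coincide exactly.
* Phase segmentation uses a 10°/s gyro-magnitude threshold with 0.25 s
  hysteresis, computed over the **maximum across the trial's sensors**: all
  sensors of a trial move at the same time, while a squat shank on its own
  never crosses the threshold. The truly-static PCA gate (2°/s) is
  deliberately separate from the segmentation threshold.

Heading reconciliation: each record's AHRS heading is zeroed at its static
posture, but a yaw component in the mounting misalignment would still leak
into joint angles. The pipeline therefore zeroes the **segment** heading —
after applying the calibration, the mean twist about lab Z over the static
window is removed — which encodes the protocol assumption that all segments
face the same direction in the upright posture. This is asserted, not
estimated; a subject standing with feet turned out would violate it.

## Metrics

RMSE, ΔROM and DRIFT operate on differences wrapped to (−180°, 180°].
ICC(2,1) (two-way random effects, absolute agreement, single measurement) is
computed from the ANOVA mean squares; ICC(3,1) is available by option. A
table with zero total variance raises instead of returning 1. SEM defaults
to total-SD·√(1−ICC), with √MS_error as an option (the source formulates
SEM without fixing the base SD); SEM% = SEM/mean·100, flagged above 10%.
ICC bands: ≥ 0.90 excellent, 0.70–0.89 good, 0.40–0.69 acceptable,
< 0.40 low.

## Simulated study

`study.run_study` draws a cohort (default 7 subjects): per-subject walking
ROMs are normal draws around the default amplitudes with typical
inter-subject SDs (clipped to ±2 SD and floored at 30% of the mean so
degenerate amplitudes cannot occur), random mountings up to 20°, and
per-subject sensor noise. Each calibration kind is repeated (default 3×)
and applied through both frame options to one walking test trial per
subject; outputs are tidy accuracy rows, per-condition aggregate tables and
per-kind reproducibility tables. All randomness flows from one master seed
through spawned child streams, so studies are bit-reproducible.
`compare_calibrations` ranks kinds by mean RMSE with percentile confidence
intervals over subject-level means — simulation replicates stand in for
inferential statistics, which are out of scope.

Problem sizes in the shipped tests and acceptance script (3–5 subjects, 2–3
repetitions, 3–5 strides per test trial) are the package's default desk
scale; every experiment accepts larger configurations unchanged.

## What passing tests do and do not show

The generator omits soft-tissue artifact, impact transients at heel strike,
magnetometer physics, ground-reaction forces and marker-based reference
noise, and its waveforms are stylized harmonics, not subject recordings.
Passing tests therefore demonstrate the *internal* correctness of the
pipeline (exactness in the noise-free limit, correct recovery under the
modelled noise, the amplitude-to-noise degradation mechanism, metric
definitions) — not the absolute accuracy that would be obtained against an
optical system on human data. Conversely, the squat degradation and the
walking calibration's distal/proximal trade-off emerge from the simulated
physics rather than being hard-coded, which is what makes them useful
acceptance properties.

## Known limitations

* The ankle uses the same generic Cardan scheme as hip and knee; no
  joint-specific axis set or sign table is applied (one is exposed in
  configuration for users matching other conventions).
* Gait events for time normalization come from the generator's ground
  truth; event detection from signals is out of scope.
* The heading-alignment assumption above fails for subjects who cannot
  stand with segments facing forward.
* Hinge-constraint ("plug and play") calibration and joint-center
  localization from accelerations are not implemented.
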