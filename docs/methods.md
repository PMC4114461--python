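# Methods

This note documents the models, conventions and numerical choices behind
`fogpose`, and what the synthetic evaluation does and does not show.

## Frames and angle conventions

All floor coordinates live in a right-handed world frame with z up.
Each camera owns a *tracking frame* anchored at the floor point directly
beneath it: its y-axis is the in-plane projection of the camera's
forward (optical) axis, x = y × z completes the basis, and headings are
measured **counterclockwise from the x-axis, viewed from above, in
degrees wrapped to [0, 360)**. The antipodal angle difference is +180°
(upper half-open range).

Compass-referenced angles follow the same rotational sense: α is the CCW
angle from magnetic North to the horizontal projection of the device
y-axis, and ψ is the CCW angle from North to the camera's forward floor
axis. With these choices the Method 1 chain is exactly

    φ = α − ψ      (heading relative to the camera yc-axis)
    θ = φ + 90°    (heading relative to the camera xc-axis)

and is self-consistent with the CCW θ convention — measuring α and ψ in
opposite senses would flip the sign of φ. A device y-axis pointing East
therefore has α = 270°, not 90°.

The mount offset γ is defined as a **clockwise** (viewed from above)
rotation of the device about the body vertical axis, which makes the
Method 1 heading err by −γ — matching the sign pattern a displaced mount
produces in the per-participant tables.

## Orientation filters (GROE / AOE)

Both filters are gradient-descent complementary filters on unit
quaternions (device → world): gyro rates are integrated and the
quaternion is nudged along the normalized gradient of the measurement
error by a step of size β per second.

* **GROE** (IMU-only) observes the gravity direction; yaw is pure
  integration in an arbitrary gauge set by the initial quaternion.
* **AOE** (MARG) additionally observes the magnetic field; its world
  x-axis is the horizontal field component (North), z up.

Defaults: β = 0.1 (GROE) and β = 0.041 (AOE), inside the range the
algorithm family recommends for consumer MEMS sensors at 100 Hz —
large enough to dominate realistic gyro bias, small enough not to pass
accelerometer noise through to the attitude. Streams are initialized
from the first sample's closed-form attitude (two-vector TRIAD for AOE,
tilt-only for GROE) rather than the identity: the normalized-gradient
step corrects large errors at a fixed angular rate (~β rad/s), so a cold
90° start would otherwise take tens of seconds to converge. AOE output
is consumed only after a 2 s warm-up. Gradients below 1e-12 are treated
as exactly zero so that a measurement consistent with the current
estimate is a fixed point. Magnetometer readings are normalized before
use; hard/soft-iron calibration is out of scope.

## Plan-view tracker

Background subtraction is depth-only: a pixel is foreground when it has
a valid return that is more than τ = 0.10 m closer than the background
reference, **or** a valid return where the background has none (the
floor behind a standing person is often beyond the 6 m range limit, so
body pixels frequently fall in the second case). The background is the
per-pixel median of 5 buffered frames, refreshed every 120 s and only
while no tracked person is in view.

Foreground pixels are unprojected and binned on a 0.05 m floor grid
(half-open cells) into per-cell maximum height, occupancy count, and
mean color when a registered color stream exists. Points below the 1.0 m
height cut-off are discarded first, which makes the maps — and
everything downstream — invariant to furniture-height scene changes.
Occupancy is conserved: its total equals the number of surviving points.

Each person is a 300-particle filter over (x, y, vx, vy) with a
constant-velocity prediction (per-step noise 0.03 m position, 0.25 m/s
velocity at 15 Hz). The observation support at a particle is a Gaussian
mixture of feature-map scores with weights (0.5, 0.3, 0.2):
occupancy smoothed by a 0.10 m Gaussian kernel and normalized to peak 1;
a height-plausibility kernel exp(−(h − h_person)²/2σ²) with σ = 0.15 m
around the height captured at track creation; and a color-match term
that is dropped (weights renormalized implicitly by the shared floor
constant) when no color is available, as in the depth-only simulation.
A small likelihood floor (1e-4) keeps out-of-map particles alive.
Systematic resampling triggers when the effective sample size falls
below N/2; ties break by particle index; all randomness is generator-
seeded. New tracks are seeded from connected components with ≥ 50
occupancy points and ≥ 1.3 m maximum height, at least 0.5 m away from
existing tracks; tracks confirm after 3 supported frames and are dropped
after 10 unsupported ones.

These tracker constants are design parameters of this implementation,
chosen once to be physically sensible at the 0.05 m cell size and 15 Hz
frame rate; the grid-filter equivalence test bounds how much the
particle approximation itself can matter (≤ 1.5 cells).

## Heading classifier

The person's plan-view height footprint in a 21×21-cell window (1.05 m
square) is normalized by the window maximum; cells outside the person's
connected component are zeroed. The 443-feature vector (441 pixels, the
normalization constant in meters, the non-zero count) feeds a 443–25–8
feed-forward network with symmetric-sigmoid (tanh) units, trained by
classic back-propagation on mean squared error against one-hot targets
in {−1, +1}: 200 epochs, learning rate 0.01, mini-batches of 32, seeded
shuffling, Xavier-uniform initialization, inputs standardized by
training-set mean/std. Class k encodes heading k·45° in the camera
tracking frame; the winning output unit rescaled from [−1, 1] to [0, 1]
is the quality score. Window-max normalization was chosen for the pixel
values because it makes templates height-invariant while the
normalization constant itself preserves the absolute scale as a
feature.

A *static heading* is proposed when the same class with quality > 0.8
persists for 3 consecutive frames. The *dynamic heading* is the
direction of the least-squares velocity fit over a 0.5 s position
window, gated at 0.3 m/s — below that speed the velocity direction of a
standing person is noise. When static and dynamic agree within ±15° for
3 consecutive frames, the static heading becomes the external reference
θs.

## Method 2 fusion across cameras

The correction angle δc = θi − θs is recomputed at every new confirmed
reference (latest wins), which tolerates slow mount drift and the GROE
yaw-gauge drift between confirmations. Heading output is withheld — not
extrapolated — before the first confirmation.

With two non-overlapping cameras and walk routes that cross between
them, δc is maintained in the *world* frame: a camera-frame θs is mapped
to the world through the calibrated camera yaw before the correction is
latched, so a reference confirmed under one camera stays valid after a
hand-off. Re-learning δc per camera would leave the stops between a
hand-off and the next alignment-friendly walking leg systematically
unconfirmed.

## Synthetic data generator

The generator emulates the accuracy-assessment protocol as its fixed
study conditions: an 8×5 m area; two depth cameras (640×480, 57°
horizontal field of view, f ≈ 585 px) at 2.25 m height, 25° downward
pitch, mounted just outside the long edge at x = 2.25 m and x = 5.75 m,
both facing +y, covering the area without overlap within the 0.4–6 m
usable depth range; magnetic North at world azimuth 25° (so ψ = 65° for
both cameras) with 60° inclination.

Participants' heights are drawn from Normal(1.742, 0.088) m. A body is a
vertical elliptical cylinder (shoulder width 0.40–0.48 m, chest depth
0.22–0.30 m) plus a head sphere (r = 0.11 m) offset 0.03–0.06 m toward
the ventral side — the anisotropy and the head offset are what make the
eight headings visually distinguishable, as real bodies are. Depth
returns get Gaussian noise with σ(z) = 0.0019·z² (the standard
structured-light range law), 2% random dropout, and invalid returns
beyond 6 m or closer than 0.4 m; the rendered silhouette is exact ground
truth.

Two scripted walks per sensor condition visit the 12 marked reference
poses (points 1–6 with predominantly left turns, 7–12 with right turns;
coordinates and facing angles on the 0.5 m floor grid). Between stops
the walker turns on the spot at 120°/s and walks at 0.8 m/s; the
trajectory is smoothed (σ = 0.15 s) so accelerations stay finite.
Human variability at each stop: position offset along the marker line
(σ = 0.08 m, clipped at ±0.22 m), across it (σ = 0.04 m), and heading
jitter (σ = 4°); the truth table keeps the *reference* marker pose, so
this variability is charged to the tracking error exactly as the
protocol charges it. The worn device has per-participant placement
jitter (σ = 6° azimuth, σ = 3° tilt) on top of the condition's nominal
mount offset (0° for the correct mounting; uniform 50–60° for the
displaced one); the IMU adds gyro noise (0.005 rad/s), a constant
per-stream gyro bias (σ = 0.005 rad/s), accelerometer noise (0.1 m/s²)
and magnetometer noise (2%). Everything is a deterministic function of
(configuration, seed) via spawned seed sequences.

Problem sizes: the replication runs 12 participants × 2 walks × 2
conditions at 15 Hz depth frames (roughly 40–50 s per walk) and 100 Hz
IMU streams; classifier training uses 4 bodies × ~38 grid positions × 8
orientations × 2 noise repetitions (~2 400 templates).

What the generator does **not** emulate: articulated limbs and gait-
phase body deformation, stooped posture, clothing and color appearance,
occlusions and multiple simultaneous people, magnetic-field
inhomogeneity, and camera synchronization error. Passing the synthetic
replication therefore demonstrates internal consistency of the full
pipeline under the stated geometry and noise — not robustness to those
real-world effects, several of which the source study itself lists as
open problems.

## Evaluation

For every scripted stop, a 1 s window of estimates centered in the
standstill interval is extracted. Position windows are accepted when
each coordinate's standard deviation is below 0.04 (interpreted as
meters and applied to position, the quantity whose 30 Hz scatter the
rule was written for); heading windows use an analogous 15° gate (a
choice of this implementation). Angular averages are circular means;
angular errors use the minimal signed difference, so all statistics are
invariant to adding 360°. Per-point tables aggregate across
participants, per-participant tables across that person's 12 stops;
unconfirmed Method 2 stops are recorded as missing and excluded, the
same way the protocol handled its algorithm failures. RMSE² equals the
mean squared error exactly, so pooled RMSEs agree across aggregations
over the same window pool.

## Known limitations

* The observation model's exact mixture form is a reconstruction; its
  parameters are sensitivity-tested only through the grid-filter
  equivalence and clutter-invariance properties.
* The toward-camera surface bias of depth silhouettes (~0.1 m) is left
  in the position estimate, as in the source protocol; the height term
  only partly compensates it.
* Method 2 depends on walking legs roughly aligned (±15°) with one of
  the eight classifier headings to confirm references; routes without
  such legs delay or prevent confirmation (stops before the first
  confirmation of a recording have no Method 2 heading).
* Single-person scenes only; track identity across cameras is by
  hand-off timing, not appearance.
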