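# Methods

## System model

The simulator reproduces a vision-aided BMI training rig: an RGB-D camera
observes a workspace of green ball targets (7 cm diameter) mounted between
the camera and a robotic arm; decoded hand-velocity vectors drive the arm's
end-effector under shared control that blends them with an attraction
toward the inferred intended target. The software chain is

scene → detection → calibration/localization → intent inference →
artificial-potential compensation → waypoints → outcome metrics.

## Target detection

A pixel is foreground iff G/(R+G+B) > 0.5; the (0,0,0) pixel is defined as
background (the ratio is otherwise undefined, and black is never a
target). Noise filtering is morphological erosion with a 3×3
all-ones structuring element — a pixel survives only when its full 3×3
neighbourhood is foreground — and border pixels, whose window leaves the
image, are cleared. Targets are interior in this rig, so erosion semantics
are preserved at the frame edge.

Clustering is divisive: all foreground pixels form one cluster, and any
cluster whose per-axis *population* standard deviation (stable down to
single-pixel clusters) reaches 20 px on x or y is split in two. The split
is a deterministic 2-means on pixel coordinates, seeded with the two
extreme pixels along the axis whose spread triggered the split (ties
broken lexicographically), iterated to a 10⁻⁶ px centroid tolerance with
at most 100 iterations; an emptied cluster is reseeded at the point
farthest from the surviving centroid. Recursion is guarded at depth 16
(more than 2¹⁶ compact clusters cannot fit in a 480×640 frame with a
20 px threshold). Returned clusters are sorted by centroid (x, then y) so
output order is reproducible. Pixel coordinates are (x, y) = (column,
row), 0-based, everywhere in the package.

When two targets project closer than the std threshold can separate, the
blobs merge and fewer clusters are returned; this regime is outside the
rig's 0.15–0.35 m separation protocol and is left undefined.

## Calibration and localization

Three linear calibrations ship as defaults so the pipeline runs without
hardware; each can be refitted from user correspondences:

* RGB→depth pixel map: `[x y 1]·B` with the 3×2 affine `B` fitted by least
  squares (`fit_pixel_mapping` rejects rank-deficient designs);
* depth linearization: distance (m) = 61.5·index + 0.1046 — the depth
  "index" is treated as a real number consistent with this line, its
  native units being undefined by the sensor;
* pixel→metre scales: X = (0.001937·d + 0.0001662)·pₓ,
  Y = (0.002072·d − 0.000227)·p_y, with pixel offsets measured from the
  optical centre (W/2, H/2) — the linear model must vanish on the optical
  axis, which fixes the otherwise arbitrary reference pixel.

The mapped depth pixel is real-valued, so the depth grid is sampled
bilinearly; nearest-neighbour sampling produces centimetre-scale jumps at
pixel boundaries. Camera→robot conversion is b = R·a + t with the fixed
rotation R = [[0,0,−1],[1,0,0],[0,−1,0]] and t = (1.24, 0, 0.05) m.
Lens-distortion models are out of scope: the calibrations are deliberately
the linear ones the rig used.

The robot-frame origin is offset 0.2 m in x and z from the arm's kinematic
frame 0; the direction of that offset is a convention in this package
(frame-0 point = robot-frame point + (0.2, 0, 0.2)), chosen so that
camera-localized targets land comfortably inside the arm's reachable
annulus.

## Kinematics

The positioning subchain is the standard 3-DOF anthropomorphic arm
(shoulder yaw/pitch, elbow) with DH lengths a₂ = 0.41 m, a₃ = 0.44 m. The
inverse solution uses the law of cosines for the elbow,
c₃ = (‖p‖² − a₂² − a₃²)/(2a₂a₃), clamped to [−1, 1] before the square
root; positions outside the annulus [|a₂−a₃|, a₂+a₃] (beyond a 10⁻¹²
tolerance) raise a workspace error. Both elbow branches
(s₃ = ±√(1−c₃²)) are exposed; "up" (s₃ ≥ 0) is the default, and neither is
claimed to be the physical arm's branch. On the vertical axis the shoulder
yaw is undefined and is set to 0 by convention rather than raising — the
singular vertical reach then returns (0, π/2, 0). All returned angles are
normalized to (−π, π].

## Shared control

Intent inference maximizes the cosine between the decoded velocity and the
direction to each candidate target, re-evaluated at every waypoint (so the
user can switch targets mid-trial); exact ties go to the lowest target id,
a zero velocity carries no intent, and a coincident target is reported as
reached. With stiffness 1 on the intended target and 0 elsewhere, the
attractive force in joint space is f_t = q_goal − q, and the induced
Cartesian step x_e(q + f_t) − x_e(q) equals target − position exactly;
this identity is asserted in the tests rather than shortcut in the code.
The potential itself is never materialized — only its induced force is
used.

The printed blending rule rescales the ideal direction to the decoded
speed (vector division being notation for that rescaling), and the inertia
recursion is implemented causally, s_k = β·Δx_k + (1−β)·Δx_{k−1}, with the
first step applied unblended. Gating: a step requires
dot(Δx_n, position − start) ≥ 0 ("moves away from the motion origin",
trivially true at the start) and dot(Δx_n, target − position) > 0 (within
90° of the intended direction, measured from the current position). A
failed gate holds position but still emits a waypoint, keeping the output
time-aligned with the velocity stream (one waypoint per velocity plus the
start). A step that would exit the reachable annulus is truncated at the
boundary along its own direction and flagged; aborting instead would bias
ensemble statistics against high-gain settings. Trials stop early within
`reach_tolerance` (default 0.02 m — a 1–2 cm deviation is tolerable given
the gripper and ball sizes) of any target.

## Synthetic data

`render_scene` inverts the calibration model exactly: each target paints a
green ellipse at its projected pixel (per-axis radii from the
distance-dependent scales) and its exact depth index into the depth grid
around the mapped depth pixel, over a distant uniform background. Scene
sampling enforces the validation protocol's separation — targets at
similar depths, at least 0.15 m apart laterally, within 0.35 m overall —
inside a frustum-safe box at ~1 m depth.

`generate_trials` emulates decoded reaches: the ideal velocity points from
the current ideal position to the trial's target with an 8 mm step (50
steps ≈ 0.4 m reach, shortened on final approach); the decoded velocity is
the ideal one rotated by a random axis-angle perturbation (axis uniform,
angle ~ N(0, 0.7 rad)) and scaled by 1 + N(0, 0.25). The defaults reflect
the weak directional fidelity of noninvasive EEG velocity decoding: a
0.7 rad angular sd leaves the raw integrated trajectory pointing broadly
at the workspace but missing individual targets, which is the regime in
which shared control is meaningful. An optional AR(1) correlation on the
perturbation is available but off by default; no claim is made that the
generator matches any particular recorded dataset's noise spectrum. The
default four-target layout places reachable targets ~0.36–0.40 m from the
start position (0.40, 0, −0.15) m in four distinct directions.

What passing tests on this generator do show: the geometric identities of
the controller, the selectivity of the attraction (intended vs.
nonintended decreases), and the qualitative shape of the (α, β) surface.
What they do not show: performance on real EEG-decoded velocities, whose
temporal autocorrelation, direction-dependent bias, and artifacts are not
modelled.

## Evaluation

The raw baseline is the integration of the decoded velocities from the
same start, without gating, compensation, or the 1.5 step gain; the gain
can be applied to the baseline via `raw_scale` for the alternative
convention, and the unscaled form is the default. Percent decrease is
100·(d_raw − d_comp)/d_raw, negative when compensation worsened the reach;
a zero-distance baseline raises an explicit undefined-baseline flag, and
flagged trials are excluded from ensemble means with a logged count. The
sweep covers the 20×20 lattice {0.05, …, 1.00}² and reports per-direction
means alongside the overall ones. The significance test is a pooled-
variance two-sample t-test, one-tailed for "intended decrease exceeds
nonintended decrease" (Welch's variant behind a flag). Chance level is
100/n_targets.

## Numerical and design notes

* Sizes used by the default test/validation runs: 60 scenes (20 each of
  2/3/4 targets), 120 trials (4×30) of 50 steps; the sweep's structural
  checks use the β = 1 row plus individual cells. These match the study
  protocol the synthetic generator emulates.
* All randomness flows through `numpy` `Generator`s seeded from explicit
  spec seeds; the pipeline derives per-stage seeds from one root seed via
  `SeedSequence` with a stable string digest.
* Erosion is delegated to `scipy.ndimage.binary_erosion` (border value 0);
  least squares to `numpy.linalg.lstsq`; the t-test to
  `scipy.stats.ttest_ind`. The clustering, calibration maps, kinematics,
  controller, and metrics are implemented here.
* The 16-bit PNG depth dialect stores index·10⁶ (quantization ≈ 3·10⁻⁵ m);
  CSV grids are lossless.

## Known limitations

* Only attraction is modelled — no repulsive/obstacle potentials.
* Non-green or overlapping targets, textured backgrounds, and lens
  distortion are out of scope.
* The decoder itself (EEG → velocity regression) is not simulated; the
  generator stands in for its output statistics only.
* Merged target blobs return fewer clusters rather than an error.
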