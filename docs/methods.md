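# Methods

This note documents the models, conventions, parameter choices and known
limitations of the gait2d pipeline. The package serves two roles: an
implementation of a single-camera sagittal markerless gait-analysis method
for children with cerebral palsy (CP), and a synthetic-walker testbed that
generates ground-truthed inputs for it.

## Angle conventions

All angles are in degrees; the walker advances toward +x, y is up. Image
coordinates (origin top-left, y down) are converted to metric y-up world
coordinates at the tracking module boundary; frames are 0-based, cycles are
half-open `[IC, next IC)`.

* **Hip flexion** — inclination of the femur (greater trochanter → lateral
  epicondyle) measured from the *downward vertical*, flexion (knee forward)
  positive. The raw observable from a lateral camera is the femur's
  inclination in the room; we report its deviation from vertical because
  that places the values on the familiar clinical scale where a vertical
  thigh reads 0° and maximal stance extension is a small negative number.
  Note this is thigh-versus-room, not thigh-versus-pelvis: a lateral camera
  cannot see pelvic tilt, so a constant offset against marker-based 3D
  systems is expected and is *not* corrected.
* **Knee flexion** — signed angle between femur and tibia (epicondyle →
  malleolus): 0° at full extension, positive flexion, negative
  hyperextension.
* **Ankle dorsiflexion** — signed angle between the foot axis (heel → toe)
  and the forward perpendicular of the tibia: 0° with the foot square to
  the shank, dorsiflexion positive.
* **Foot orientation** — angle of the heel→toe line to the horizontal,
  positive when the heel is higher than the toe ("heel up"). For any
  planar chain these four are linked by the identity
  `foot = knee − hip − ankle`, which the simulator exploits and the test
  suite asserts.

## The synthetic walker

### Joint-angle templates

One gait cycle of each joint is a periodic cubic spline through editable
keyframes (value and slope continuous across the 100 %→0 % wrap). The
*normal* template is a slow-walking pattern (cycle 1.1 s, step 0.38 m,
hence 0.69 m/s — the defaults match the means of the reference CP cohort,
whose self-selected speeds are far below typically developing children).
Because the stride is short, the hip and tibia excursions are scaled to
slow-gait magnitudes (hip ≈ +17° at contact to −10° in late stance) while
the knee keeps its full ~60° swing-flexion range; foot orientation follows
the three rockers (heel-down −15° at contact, flat 10–40 %, heel rise from
~41 % to toe-off at 60 %).

The six pathological templates are additive offset curves on top of the
normal template ("offsets all zero" recovers the normal template exactly):

| template | intent | key choices |
| --- | --- | --- |
| `true_equinus` | toe-walking, ankle plantarflexed throughout the cycle, knee/hip extended in stance | ankle offset ≈ −15…−24°; slight hip/knee extension bias; foot heel-up from contact |
| `jump` | toe-walking, plantarflexed ankle with flexed knee and hip | ankle ≈ −14…−22°, knee +15° and hip +12° in stance |
| `apparent_equinus` | toe contact *without* abnormal ankle range, driven by knee/hip flexion | ankle offset small (−4…−7°); knee +20…24°, hip +8…12°; stance ankle maximum stays in the normal range (~+9°) |
| `crouch` | excessive dorsiflexion with excessive knee and hip flexion, heel-contact gait | ankle +6…12°, knee +28…32°, hip +20…28° |
| `short_hamstring` | increased knee flexion at contact and terminal swing, otherwise near normal | knee +5° at 0 %, +8° at 88 %, 0 mid-cycle |
| `hyperextension` | foot flat from contact (no first rocker), plantarflexed at contact with limited stance dorsiflexion, knee hyperextended in stance (plantarflexion–knee-extension couple) | knee −14° midstance (stance minimum ≈ −7°), ankle offsets shaped so foot orientation ≈ 0 through stance |

A seeded smooth perturbation (periodic spline through random keyframes,
default pointwise SD 2°, a typical inter-trial kinematic variability) is
added per joint; it depends only on the seed, not the pattern, so two
specs with the same seed stay comparable.

### Forward kinematics and ground contact

Each side follows the same curves half a cycle out of phase (foreground
side leads by 0.4 cycles so the trial has lead-in/lead-out margin around
every contact). During stance the foot is *anchored*: the heel is the pivot
from initial contact through the flat phase, and the pivot hands over to
the toe at the heel-rise (the last upward crossing of a 0.5° heel-up
threshold, which ignores transient spline overshoot after the first
rocker); toe-walking templates anchor the toe from contact. Anchor
positions advance by one step length per contact, so the realized step
lengths and the 2·step/cycle walking speed are exact by construction, as is
the zero velocity of the anchored marker — the properties the event
detector and the spatio-temporal code are validated against. The trochanter
during stance follows from the anchored chain; swing-phase trochanter
motion is a quintic matching position, velocity *and* acceleration at both
stance boundaries. The acceleration matching matters: it makes the landing
foot decelerate into contact over a realistic terminal-swing timescale
(velocity and acceleration reach zero together at touchdown), which is what
lets a velocity-threshold contact detector land within a frame of the
truth. Each leg carries its own trochanter trajectory (the two agree to a
few centimetres); the pelvis is not modelled.

Two deliberate imperfections are accepted: the per-leg trochanter advances
monotonically for six templates but shows a transient retraction of ≤ 1 cm
just after contact in the hyperextension template (the
plantarflexion–knee-extension couple briefly braking pelvic progression),
and walking direction is fixed left-to-right with single passes only.

Closure is exact: recomputing the four angles from the generated landmarks
reproduces the input curves to numerical precision, because stance frames
are built by inverting the same chain the kinematics module measures.

### Noise model and rendering

Measurement noise is i.i.d. Gaussian jitter per landmark, frame and
coordinate (default SD 5 mm — deliberately pessimistic for color-blob
tracking at 130 px/m) plus per-frame side dropout (default 0). The renderer
draws a green background (with ±3 % per-frame brightness jitter emulating
exposure variation), the background leg first and the foreground leg over
it: thigh/shank strokes, a sock-shaped octagon whose extreme tips are
exactly the heel and toe (the tip wedges are symmetric about the foot axis
so a local centroid is unbiased), and near-black pen-mark disks. Frames are
960×540 at 130 px/m — enough to hold the whole 7 m walkway. An optional
depth-proxy label map (background / far leg / near leg) stands in for the
RGB-D camera's depth image.

## Tracking

Feet are identified by sock color alone (hue/saturation/value ranges
matched to the renderer's palette; real video needs re-tuning through the
same config). Heel and toe are the blob's extreme points along its
*principal axis* oriented by the walking direction — at push-off angles a
pure image-x extreme would catch a sock corner — refined to sub-pixel with
a 5-px-neighborhood centroid across the axis and a half-pixel edge term
along it. Pen marks are assigned to the foreground leg via the depth proxy
when present (nearest-to-previous-frame matching otherwise) and ordered
top-to-bottom as trochanter/epicondyle/malleolus. Background-leg pen marks
are *not* tracked: behind a single lateral camera they are frequently
occluded by the near leg, so video-derived joint kinematics are produced
for the foreground side, while both feet are tracked for events and
spatio-temporal parameters. Trajectory-level (CSV) input carries both
sides in full.

Gaps of ≤ 5 frames are linearly interpolated and flagged; trajectories are
smoothed with a zero-lag 4th-order Butterworth low-pass at 6 Hz before any
differentiation. Trials in which fewer than 80 % of frames have both feet
validly detected are rejected with the machine-readable reason code
`feet_unclear` rather than analyzed — mirroring clinical practice of
excluding recordings whose images do not allow reliable foot
identification.

## Events

Initial contact is the earliest instant at which either the heel or the toe
becomes stationary: horizontal speed below `v_thresh` sustained for
`dwell` frames, one contact per below-threshold episode. Using the earlier
of the two markers is clinically essential: the heel stops first at heel
strike, the toe first in toe-walkers. Toe-off is the first sustained rise
of the toe's speed after its stationary episode (in heel-strike gait the
toe only becomes stationary at foot-flat; a naive "first movement after
contact" rule would fire during the first rocker). Sub-threshold masks are
morphologically closed for gaps shorter than the dwell so a one-frame noise
spike cannot split a contact in two.

Defaults: `v_thresh` 0.10 m/s, `dwell` 3 frames at 30 fps, velocities by
central differences on the smoothed tracks. These were set so that on
noise-free synthetic trials detection recovers true initial contacts within
±1 frame and toe-offs within ±2 across all seven templates; a strict "zero
velocity" is unattainable on differentiated sampled signals, and lower
thresholds interact with the zero-lag filter's backward smearing of the
swing acceleration, firing toe-off several frames early.

## Spatio-temporal parameters

Step length is the horizontal distance between the foreground heel at its
initial contact and the background heel at the *next* contralateral
contact (pairs in the wrong order are skipped). Gait speed is the
trochanter's forward progression between the first and last contact of the
trial; the default estimator is the least-squares linear trend over that
window with one gait-harmonic regressor (period = mean contact spacing).
For a linearly advancing trochanter this equals displacement over elapsed
time exactly, but it is robust to single-frame uncertainty in the bounding
contact frames — raw endpoint displacement doubles to quadruples the error
because the chain-driven trochanter moves fastest exactly at contact.
Endpoint-displacement and cadence (mean step length / mean step time)
estimators remain available behind a switch. Cohort tables aggregate over
participant-side rows (sample SD, missing entries skipped).

## Features, normative band and classification

Per cycle, then averaged per side: hip maximum extension and ROM; knee at
initial contact, loading-response peak (maximum over 0–15 % of the cycle —
the window is a convention, the source descriptions leave it open), peak
stance extension (minimum flexion between the loading-response peak and
toe-off — negative for a hyperextending knee; the printed negative values
in published cohort tables motivate reading "max in stance" as peak
extension), swing maximum and ROM; ankle dorsiflexion maxima in stance and
swing; mean foot orientation over cycle samples 10–30 inclusive.

The normative band is the pointwise mean ± SD of the normalized curves and
of every scalar feature across ≥ 5 normal-pattern trials (default: 10
simulated trials with default noise and variability). Classification reads
the curves against a 1-SD corridor, following the convention of judging
mild deviation as "within 1 SD of laboratory normal":

1. *toe-walking* if mean foot orientation over 10–30 % exceeds +10°
   heel-up, or the first rocker is absent (foot orientation never below
   −2° in 0–10 %);
2. *ankle*: plantarflexed throughout stance (stance maximum < 0°) /
   normal / excessive (> band mean + 1 SD);
3. *knee and hip posture*: flexed if the stance feature exceeds band
   mean + 1 SD, else extended;
4. mapping: toe-walking + plantarflexed → type I (knee/hip extended) or
   type II jump (flexed); toe-walking + normal ankle + knee and hip
   flexed → type III apparent equinus; excessive dorsiflexion + knee and
   hip flexed → type IV crouch; anything else → unclassified-mild.

Every comparison is recorded in an ordered rule trace. Deviation flags
(increased knee flexion at initial contact, decreased terminal-swing
extension, knee hyperextension in stance, absent first rocker, and the
plantarflexion–knee-extension couple = hyperextension with stance ankle
maximum ≤ +5°) describe the mild patterns that escape the four types. All
cutoffs are configuration values; the source classification is an expert
judgement without published numbers, so the defaults are design choices
validated against the templates that encode the corresponding clinical
descriptions. A participant-level label would be the more affected side's
label; the package reports per side.

## Validation design and problem sizes

* **Kinematic accuracy** (20 rendered trials, patterns in rotation, seeds
  derived from the CLI seed, default 5 mm jitter, 2 cycles per trial at
  960×540): average per-joint RMSE between pipeline-estimated and
  ground-truth normalized curves, both normalized on the ground-truth
  contact frames. Using the true events isolates measurement error — the
  quantity a concurrent-validation RMS difference describes — while event
  accuracy is assessed separately (±1 frame noise-free; spatio-temporal
  errors under noise). Typical results: hip ≈ 0.5°, knee ≈ 0.8°,
  ankle ≈ 1.1°.
* **Spatio-temporal accuracy** (40 simulated trials, 3 cycles each):
  mean absolute difference between automatically detected and
  ground-truth-contact-based gait speed (≈ 0.001 m/s) and step length
  (≈ 0.002 m).
* **Property suites**: simulator/kinematics closure < 0.5°, angle
  operations vs an independent arctangent oracle to 10⁻⁶ °, 100 % IC
  recall at ±1 frame noise-free, template-fidelity of the classifier, and
  rejection of 30 %-dropout trials with the documented reason code.

Problem sizes (20/40 trials, 2–3 cycles, 960×540 frames) keep the full
validation under a minute on one CPU while leaving every estimate's
uncertainty far from the acceptance margins.

## What the synthetic data does and does not show

The generator reproduces the *geometry* of the acquisition scenario —
colors, landmark scheme, scale, frame rate, occlusion order, contact
mechanics, inter-trial variability, jitter and dropout — so passing tests
demonstrate that segmentation, tracking, event detection, kinematics and
classification are internally correct and mutually consistent at realistic
signal-to-noise. It does **not** render skin, clothing, lighting gradients,
motion blur, lens distortion, soft-tissue artifact, real depth images, or
out-of-sagittal-plane motion (coronal/transverse deviations are explicitly
out of scope); color thresholds tuned to the renderer will need re-tuning
on real video, and accuracy on real recordings cannot be inferred from
these figures. The hip convention's offset against pelvis-referenced 3D
systems is inherent to single-camera acquisition and is documented, not
corrected.
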