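# Methods

`gaitval` emulates a three-system clinical gait study on synthetic data
and quantifies inter-system agreement. This note records the model, the
defaults, the numerical choices, and what the synthetic design can and
cannot say about real data.

## The measurement problem

Clinical gait analysis compares three classes of systems:

* **MB** — marker-based optical capture, the gold standard, which
  delivers per-segment rigid poses (4×4 homogeneous transforms);
* **M-ML** — multi-camera markerless capture, which reconstructs the
  same kind of 3D segment poses from video;
* **S-ML** — a single-camera (two independent monocular smartphone
  views) markerless pipeline, which only ever sees 2D keypoints in
  pixels and must recover angles, events and distances from planar
  geometry plus a pixel-to-meter calibration against a reference object
  of known length (0.46 m) in the scene.

The outcomes are five spatiotemporal parameters (gait speed, step
length, stride length, stance time, swing time) and five lower-limb
angle traces (hip and knee in the sagittal and frontal planes, ankle
sagittal), each reduced to one representative gait cycle per trial,
time-normalized to 101 points (0–100 % of the cycle, the biomechanics
convention). Agreement is summarized with ICC(2,1) — two-way random
effects, absolute agreement, single measurement — for the
spatiotemporal parameters, interpreted with the conventional bands
(< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9 excellent,
boundaries left-closed), and with RMSE over normalized cycles and over
per-cycle extrema for the kinematics.

## Synthetic gait model

A subject is a pelvis–thigh–shank–foot rigid chain per leg. The pelvis
translates along the progression axis `x` at constant speed with
small periodic oscillations: vertical (two and four cycles per stride,
amplitudes 0.032 m and a solved second harmonic, both side-symmetric),
lateral sway (one cycle per stride, 0.03 m) and pelvic obliquity (roll
about `x`, 6°, lowering each hip toward its stance side). Axes:
`x` = line of progression, `y` = vertical up, `z` = mediolateral to the
subject's right.

Joint angles are periodic functions of the normalized cycle phase,
stored as truncated Fourier series (up to 12 harmonics). The left leg
runs the right leg's profiles half a cycle later. Events are defined
*analytically* — heel strike at phase 0, toe off at phase equal to the
stance fraction — so ground truth is exact rather than detected; there
is no ground-reaction or contact simulation.

Pace obeys `speed = step_length × cadence / 60`; any two of the three
determine the third. Defaults: speed 1.091 m/s and step 0.609 m (the
marker-based cohort means the bench is parameterized on), giving
cadence 107.5 steps/min and stride 1.218 m; stance fraction 0.6676.

### Event-locked default profiles

The default profiles are *designed so that coordinate-based event
detection is exact on noise-free data*, because the generator's job is
to provide an unambiguous reference:

* every joint profile has exactly zero phase-derivative at the
  heel-strike and toe-off phases (a linear constraint enforced through
  a null-space parameterization of the Fourier fit);
* profile shapes come from physiological knots (hip flexion peaking at
  contact and extending through stance with a fast swing recovery; a
  knee loading-response bump, near-extension in terminal stance,
  ~20° at toe-off and a 61.5° mid-swing peak; a foot that is
  heel-down at contact, flat through mid-stance and steeply pitched at
  push-off), splined periodically and projected onto the constrained
  Fourier basis;
* the ankle profile is derived from world foot-pitch targets via the
  closed-form shank tilt (hip − knee): through late stance the toe
  *rides* a gently descending height target into a strict minimum at
  the toe-off phase, kept 2–3 mm inside the foot's geometric reach so
  the target stays attainable;
* a final two-unknown root solve (a first-harmonic ankle correction and
  the pelvis second vertical harmonic) zeroes the pelvis-relative toe
  velocity at the toe-off phase exactly, absorbing the small residual
  couplings from frontal-plane profiles and obliquity.

Sagittal peak targets are pinned to the reference means (hip +26.44 /
−12.57°, knee 61.53 / 1.75°); frontal hip and knee profiles are single
negative-cosine shapes rescaled to the reported peak ranges
(−3.57…+7.99° and −2…+9.78°). The pelvic obliquity exists for a
geometric reason: with a side-symmetric chain, the mid-stance extended
leg would otherwise put the heel lower than at its own contact; rolling
each hip down toward its stance side makes each heel lowest (within
5 mm, the depth of the contact plateau) at its own heel strike.

Two deliberate distortions of textbook gait follow from the locks: the
foot is strongly heel-down pitched at contact (~38°) and the knee is
more extended at toe-off (~20° instead of ~40°). Both are documented
trade-offs that buy frame-exact noise-free event recovery.

`sagittal_only=True` zeroes the frontal profiles, the sway and the
obliquity: the geometry under which a lateral planar view is exact.

## Cameras and calibration

Projection is an ideal pinhole (1920×1080, 60 Hz, no lens distortion —
the monocular error mechanisms of interest are perspective and depth
scaling, not distortion). The lateral camera sits on the subject's
right, 3 m from the midline at the walkway center, optical axis
perpendicular to the progression line; the frontal camera sits 2 m past
the walkway end looking back along it. Image convention: origin
top-left, u right, v down. Default focal length 1200 px (a wide
smartphone lens; keeps tall subjects framed across several strides).
An `orthographic` mode replaces the perspective division by the
far-field scale `focal/<nominal depth>` — the limit a perspective
camera approaches as it is moved away with the focal length scaled up —
used wherever a test needs projection without perspective confounds.
Frames where any keypoint leaves the image are flagged, never clipped;
analysis uses the largest contiguous fully-visible run.

Metric scale is recovered the way a video-only pipeline does it: a
0.46 m reference of known length in the scene gives one meters-per-pixel
factor, valid only at the reference's depth. The resulting
similar-triangles error — measured length scales by
`d_ref / d_subject` — is itself one of the validated mechanisms.

## Angle computation

**Transform route (MB, M-ML).** Relative rotation parent→child, Cardan
decomposed in the clinical sequence: mediolateral axis first
(flexion/extension), then anteroposterior (ab/adduction), then
longitudinal (axial rotation) — intrinsic z-x-y in the walkway axes
with closed-form extraction and an explicit gimbal-lock error (the
second angle never approaches ±90° in gait). Signs follow the clinical
reporting convention: flexion, dorsiflexion and abduction positive on
both sides. The foot segment frame coincides with the shank frame in
the neutral pose, so neutral dorsiflexion decomposes to zero without an
explicit 90° offset; the transverse-plane angle is computed but is not
part of the reported outcome set. Hip = pelvis→thigh, knee =
thigh→shank, ankle = shank→foot.

**Planar route (S-ML).** Sagittal angles from the lateral view, frontal
from the frontal view. Hip flexion is the thigh's tilt from image
vertical (a declared assumption; the alternative trunk reference is not
used). Knee flexion is the signed deflection of the shank from the
extended thigh line (collinear = 0). Ankle dorsiflexion is the signed
angle between the shank line (knee→ankle) and the *sole line*
(heel→big toe) minus the 90° neutral; the sole line, not ankle→toe, is
parallel to the foot axis. Frontal-plane hip/knee angles use the same
constructions on the frontal view with side-dependent signs so
abduction is positive bilaterally.

## Event detection

**3D (MB, M-ML), coordinate-based.** Heel strikes are local maxima of
pelvis-relative anterior heel displacement, toe offs local maxima of
pelvis-relative posterior toe displacement; minimum inter-peak distance
is half the expected stride (estimated from the signal's dominant
period when not given), prominence 10 % of the signal range, and
extremum locations are refined to sub-frame precision by parabolic
interpolation. A stationary subject returns no events.

**2D (S-ML), threshold-based.** Heel strikes: mid-hip-relative heel
extrema in the image plane, as above. Toe off: within each same-side
cycle, the toe-height trace (smoothed with a 9-sample quadratic
Savitzky–Golay filter, with noise scale estimated from the
raw-minus-smoothed residual) first *sustains* a rise of 0.02 m above
its stance-phase baseline (lowest-quartile median) for 2 frames; the
event time is the last sample still within a noise band
(max(2 mm, 2σ)) of the pre-crossing minimum — the last instant of
ground contact — sub-frame refined. The initial post-contact descent is
skipped so the heel-strike toe-up posture cannot trigger the crossing.
Detection runs on the device clock; the emulated audio-synchronization
offset between the smartphone pair and the lab (0.12 s) is removed by
aligning right heel strikes against the reference system, anchored on
the nearest strike because the monocular view covers a shorter span.

**Spatiotemporal definitions.** Stride length = same-side heel-to-heel
distance along the progression axis over one cycle (positions read at
the sub-frame event times by linear interpolation, since the heel moves
at pelvis speed at the relative extremum); step length = contralateral
anterior distance at successive contacts; stance = HS→TO, swing =
TO→next HS (their sum is the stride time by construction); gait speed =
stride length / stride time. For S-ML, positions are pixels times the
calibration factor. The representative cycle is the one whose midpoint
lies nearest the walkway center (the stand-in for the force-plate
crossing); if heavy noise leaves that cycle without a toe-off, the
nearest complete cycle substitutes.

## Study emulation

Sixteen subjects (stature ~N(1.6925, 0.0919²) m, segment lengths scaled
proportionally; speed ~N(1.091, 0.093²) m/s; step ~N(0.609, 0.048²) m)
each walk twice (7 s at 60 Hz along a 10 m walkway, trial-specific
starting phase); the two trials are pooled as independent observations
(32 cycles). Noise presets: `ideal` (all zero), `bench` (small), and
`realistic` (default: MB pose jitter 0.5°/2 mm, M-ML 2°/5 mm, S-ML
pixel jitter 3 px with confidence scores that decay with the injected
perturbation, refined by confidence-weighted interpolation below
confidence 0.3 within ±5 frames). The gold standard is deliberately
modeled as truth *plus* small noise — its role is a reference with
known sub-degree error, not perfection; `ideal` makes it exact for
oracle tests. ICC matrices are two columns (each test system against
the reference), matching a two-ICC-column report layout. Curve RMSE is
computed per cycle then averaged (pool-then-RMSE is available behind
`rmse_aggregation="pooled"`). Everything is deterministic under a fixed
seed via spawned seed sequences per subject/trial.

## What the bench does and does not show

The generator reproduces the *mechanisms* of monocular error —
perspective foreshortening from out-of-plane limb motion, depth-scaling
of lengths, toe-off threshold sensitivity to keypoint jitter, the
swing-phase's inherent vulnerability to temporal jitter (it is half as
long as stance, so equal jitter doubles its relative error) — and the
exactness of the 3D route on clean data. It does **not** model
occlusion, clothing, pose-estimator bias fields, soft-tissue artifact,
marker placement error, pathological gait, or ground-reaction dynamics.
Passing tests therefore validate the *computational pipeline* and the
relative ordering of error mechanisms, not the absolute accuracy any
real system would achieve. Two observed behaviors worth naming:

* under perspective, lateral body sway modulates subject depth, which a
  monocular view cannot distinguish from vertical motion; this shifts
  the apparent toe-height minimum and biases S-ML toe-off by several
  frames — a faithful rendition of the monocular depth ambiguity, and
  the reason S-ML temporal parameters band lowest in the default study;
* at 60 Hz, swing time (~22 frames) measured by two *independent*
  detectors is bounded by their ~0.3-frame sub-frame scatter, capping
  the attainable zero-noise swing ICC near 0.97.

## Numerical choices

* Rotation orthonormality tolerance 1e-6 (input validation), gimbal
  guard 1e-6 rad from ±90°.
* Fourier fitting: 2048-point dense grid over a periodic cubic spline
  through the knots (fitting the spline, not the knots, avoids
  interpolation ringing); equality constraints via particular solution
  + null space.
* The toe-off lock solves two unknowns with `scipy.optimize.root` to
  residuals < 1e-9 m/cycle; ride and lock are iterated twice so the
  pelvis correction feeds back into the ankle-height profile.
* Event comparison tolerances are expressed in frames at 60 Hz
  (1 frame = 16.7 ms).
* Problem sizes in tests and the acceptance script (cohorts of 16×2,
  50 random round-trip patterns, 200 ICC oracle matrices, 25 noise
  replicates per sigma) are the package's own defaults and keep the
  whole battery within tens of seconds.
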