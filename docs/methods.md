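# Methods

## Problem setting

`kinagree` compares two simultaneously recorded skeleton-kinematic streams
of the same subject on a joint-angle basis: a low-cost VR-tracker stream
(nominally 90 Hz, solved by inverse kinematics from a handful of tracked
points) against a marker-based optical reference stream (100 Hz), treated
as ground truth. The use case is ergonomic risk assessment, where
observational schemes such as RULA and REBA score postures from joint-angle
threshold bands, so the quantity that matters is the sample-wise joint-angle
error, not positional error.

Because the two systems are closed commercial products, they cannot be
synchronized at acquisition time, they run at different rates, their
skeletons are referenced differently, and the VR stream suffers recording
interruptions and solver-induced systematic errors. The pipeline therefore
reconstructs comparability step by step, in a fixed order that the runner
enforces:

1. origin shift to the hip center (re-referencing),
2. derivation of 16 joint angles,
3. resampling to the reference rate, low-pass filtering, interpolation of
   isolated drop-outs,
4. neutral-zero offset correction,
5. global time offset from the T-pose preamble,
6. segmentation into annotated movements,
7. per-segment resynchronization (coarse DTW + fine FFT),
8. systematic polynomial correction,

followed by agreement statistics on the concatenated linked segments.
Steps 1, 4 (re-referencing) and 5, 7 (synchronization) exist only for the
comparison itself and can be skipped with the production flag.

## The skeleton and the angle model

Both streams use one unified 20-joint skeleton (hip_center root, spine
chain to the head, two arms, two legs) in a right-handed frame with z up
and x anterior. Joint orientations are unit quaternions (Hamilton
convention, scalar first) relative to the neutral-zero stance, in which all
orientations are the identity.

Sixteen angles are computed with three methods:

* **Plane-referenced angles** (neck, chest, pelvis, shoulder elevation,
  elbow azimuth, hip flexion). Anatomical reference planes are attached
  locally at a joint: the torso axis between two orienting joints gives the
  transversal-plane normal; the shoulder line (hip line for lower-body
  origins), orthogonalized against the torso axis, gives the sagittal
  normal; the anterior (frontal) normal completes the right-handed triad.
  The vector to a target joint is projected into one plane and measured as
  a signed angle from a neutral direction. Convention anchors: a hanging
  arm has shoulder elevation 0°, a straight-forward arm +90°, a
  straight-backward arm −90°; left lateral tilt is positive. For the
  pelvis, whose measured vector coincides with the torso axis, the axis is
  held from a calibration (neutral) frame.

  The direction of a projection with a tiny in-plane norm is unreliable: a
  hanging arm's azimuth flips by 180° under infinitesimal perturbation.
  Samples whose in-plane projection is below `min_projection` (default
  0.02 m, roughly 3.5° of limb deviation) are flagged missing rather than
  reported as noise.

* **Three-point flexion** (elbows, knees). The interior angle at the
  middle of three joint positions by the law of cosines on the Euclidean
  segment lengths, complemented to `180° − α` so a straight limb reads 0°.
  Note this measurement is folded: it cannot distinguish flexion from
  hyperextension.

* **Quaternion relative rotation** (head inclination and lateral
  inclination). The relative rotation `q12 = q1⁻¹ ⊗ q2` between the head
  and its predecessor joint is decomposed into intrinsic y–x–z Euler
  angles; the pitch term is the sagittal inclination (forward positive),
  the roll term the lateral inclination (left positive). Samples within
  0.5° of gimbal lock are flagged.

All angle definitions (target, origin, orienting joints, planes, signs)
are declarative `AngleDefinition` records and can be overridden.

## Preprocessing

The VR stream is first linearly regularized onto its nominal 90 Hz grid
(output samples farther than one step from any valid input are flagged),
then Fourier-resampled to the 100 Hz reference rate. Both streams are
filtered with a second-order Butterworth low-pass at 3 Hz, applied
zero-phase (forward–backward): the comparison is sample-wise, so filter
phase lag would masquerade as time shift. Angles that can cross ±180° are
unwrapped before filtering and re-wrapped. Runs of at most
`max_isolated_gap` missing samples are filled linearly; longer runs stay
flagged.

The neutral-zero method assigns 0° to every angle in the relaxed upright
stance. The per-angle offset is the mean over the first `neutral_window`
seconds (default 2 s) of the recording, which the protocol guarantees to be
neutral standing. At least half the window's samples must be valid —
an angle undefined in the neutral posture (the azimuth of a hanging arm)
must not receive an offset from a few stray marginal samples, and simply
keeps none.

## Synchronization

The VR clock is reconstructed in three passes, all reporting the *lag* of
VR content relative to the reference (the applied correction subtracts it):

1. **T-pose preamble.** The protocol opens with three 90° elbow-flexion
   pulses in T-posture. A preamble is accepted when at least three pulses
   exceed half the pulse amplitude in each stream; the global offset is the
   cross-correlation peak of the elbow-flexion series over the preamble.
2. **Coarse per-segment shift (0.5 s < |shift| < 2 s)** by dynamic time
   warping. The warping path is computed on both streams decimated to
   20 Hz under a slanted Sakoe–Chiba band (±3 s, widened to cover the
   window-length difference). Matched pairs on *diagonal* stretches of the
   path (one-to-one matching, runs of at least 5 steps) measure clock
   offset; staircase stretches encode speed differences and are excluded.
   Three robustness measures matter in practice: (a) only pairs where the
   reference signal is actually changing are averaged — flat dwell matches
   arbitrarily; (b) both windows carry ±2.5 s of neighbor context, while
   the averaged pairs are restricted to the movement core — this
   disambiguates the period aliases of a repeated-movement protocol;
   (c) the estimate is the mean of the forward and the time-reversed
   alignment, cancelling the backtrack's one-sample orientation bias.
   Normalization uses one shared center and scale (from the reference
   window): both series carry the same angle in degrees, and per-series
   normalization of windows with different dwell fractions would introduce
   a vertical offset that DTW converts into a horizontal (time) bias.
   A shift outside [0.5, 2] s is reported but not applied.
3. **Fine shift (< 0.5 s)** from the frequency-domain cross-correlation
   peak with parabolic sub-sample refinement, iterated up to three times
   because a true lag near the search edge leaves a residual after one
   pass. A normalized peak below 0.2 flags low confidence.

Shifts are applied cumulatively (each segment starts from the previous
total; configurable), the sync angle of a segment is its most-moving linked
angle (elbow flexion for unlinked segments), and inter-segment gaps inherit
the nearest preceding shift. The resynchronized VR series is re-interpolated
onto the reference grid piecewise per segment, so per-segment shifts cannot
reorder samples.

## Systematic correction

Even after offset correction, the differing inverse-kinematics solvers
leave smooth angle-dependent over/underestimation. Per angle, the
sample-wise difference (VR − reference) over the pooled linked segments of
all subjects is regressed on the VR angle value with a polynomial of
degree 12. The fit uses a Chebyshev basis on the rescaled fit domain —
raw monomials are numerically hopeless at degree 12 — and evaluation
outside the fit domain clamps to the endpoint values, because extrapolating
a high-degree polynomial is explosive. The fitted function is subtracted
per subject. At least `10 × (degree + 1)` aligned samples are required;
rank-deficient supports reduce the degree with a warning.

Two application protocols exist: `pooled` fits on all subjects and applies
to each (the default), and `held_out` fits on the other subjects before
applying — the honest protocol when the correction is evaluated on the
same movements it was trained on. `select_degree` chooses the degree by
k-fold cross-validation (interleaved folds so every fold spans the domain);
a higher degree must beat the best RMS by a relative 10⁻³ or the lower
degree wins, so chance CV fluctuations on structureless differences do not
inflate the degree.

## Agreement statistics

On the aligned, corrected, concatenated linked segments:

* **IPR and accuracy class**: the 5th–95th percentile interval of the
  differences; class from max(|p5|, |p95|): ≤ 10° good, ≤ 15° medium,
  else poor.
* **Concordance correlation coefficient**
  `ccc = 2σ_qv / ((μ_q − μ_v)² + σ_q² + σ_v²)` with population (1/n)
  moments; McBride bands: < 0.90 poor, < 0.95 moderate, < 0.99
  substantial, ≥ 0.99 almost perfect (closed on the left).
* **Modified Bland–Altman**: mean difference and limits of agreement
  (mean ± 1.96 SD) from all samples, with the *reference* angle on the
  x-axis rather than the two-system average, since the reference is
  treated as ground truth; the plotted scatter is a seeded subsample of
  2500 unique indices (uniform without replacement by default; a
  Gaussian-over-index-positions mode exists).
* **RoM summaries** (quartiles, mean, SD, min, max) per system, and
  half-open ergonomic threshold banding (e.g. neck flexion 0–10°,
  >10–20°, >20°).

The difference sign is VR − reference: positive means the VR stream
overestimates.

## The synthetic-data generator

No deposited recordings exist, so validation rests on generated sessions
with recorded ground truth. The generator emulates the study protocol:
5 s neutral stance, the T-pose preamble (three 90° elbow pulses), then
twenty scripted movements, each as three cosine ramp–hold–return
repetitions separated by neutral dwells, annotated and linked to angles per
the movement catalogue. Default amplitudes are plausible ranges of motion
(head inclination 40°, lateral 30°, shoulder elevation up to 170°, elbow
flexion 140°, knee flexion 120°); ramp time scales with amplitude
(`max(1 s, amplitude/100°·s)`) so larger excursions take proportionally
longer at "normal speed". During the elbow-curl movement the supporting
shoulder elevation (60°) is *sustained* across the whole segment and
settles before the repetitions start, keeping the arm azimuth well-defined
throughout.

The skeleton is posed by forward kinematics from per-joint rotation
channels; each measurable angle has a channel constructed so that the angle
recomputed from the generated frames equals the scripted trajectory exactly
(bone lengths are conserved to machine precision). Anthropometry defaults
to standard segment-length fractions of stature.

The degradation model re-times the stream to 90 Hz with clock jitter
(SD 0.5 ms) and injects, all recorded as ground truth:

* a start delay (content lag);
* **interruptions**: frames across a span are deleted and subsequent
  timestamps compressed by exactly the span — these produce the time
  shifts the resynchronization must recover;
* **drop-outs**: frames deleted with the clock left intact — visible as
  inter-frame gaps (the irregularity detector flags gaps > 1.5 nominal
  steps) but producing no shift;
* per-angle neutral offsets (SD 2°). Offsets respect what the measurement
  can express: flexions are folded non-negative measurements, so their
  neutral offsets are drawn non-negative (a neutral posture cannot sit
  below the anatomical zero), and azimuths receive none (their neutral
  value is undefined, so an offset would be unobservable and
  uncorrectable);
* a smooth systematic distortion `θ' = θ + g(θ)` shared across subjects
  (as a solver-induced error would be): a cubic with `g(0) = 0` and a
  linear slope of guaranteed magnitude 0.02–0.06 — the modeled phenomenon
  is a consistent over/underestimation, not noise;
* band-limited additive angle noise (Gaussian, low-pass shaped at 6 Hz so
  it survives the 3 Hz pipeline filter only partially; SD 1°);
* tracker-jump artifacts (joints displaced ≥ 0.5 m for a span) and
  rigid-limb episodes (a channel frozen for a span);
* isolated sample drop-outs (NaN positions).

Everything is deterministic under the seed.

### What the generator does not emulate

Channel noise is injected on joint angles, not on tracker positions fed
through an inverse-kinematics solver, so cross-joint error correlations of
a real IK chain are absent. Soft-tissue artifact and tracker slippage are
represented only through the generic distortion g(θ). The movement
repertoire is scripted and periodic, which makes synchronization *harder*
in one specific way (period aliasing) and easier in others (clean dwells).
Passing recovery tests therefore demonstrates that the pipeline's
estimators are correct and unbiased under controlled degradations, not
that a specific hardware pairing achieves a given accuracy.

## Numerical choices

* Percentiles use linear interpolation; CCC uses population moments.
* Three-point flexion clamps the cosine into [−1, 1] (with a warning
  beyond 1e-9) and is ill-conditioned within ~1° of a straight limb,
  where float64 rounding alone moves the angle by more than 1e-6°.
* Quaternions are normalized on construction and relative rotations are
  hemisphere-fixed (non-negative scalar part).
* The DTW pass decimates to 20 Hz (0.05 s resolution); the fine FFT pass
  restores sub-sample accuracy, so the coarse grid only needs to land
  within the fine search window.
* Reference recordings must have constant frame spacing within 1e-9 s;
  VR recordings may be irregular.
* Correction fits are bit-reproducible for identical inputs and carry a
  content hash; every pipeline output embeds the configuration hash and
  seed.

## Problem sizes

The default validation setup uses full 20-movement sessions of roughly
230 s at 100 Hz (about 23,000 frames) and cohorts of 3 subjects; shift
recovery is assessed over 100 seeded trials per run. These sizes give
every angle several thousand linked samples, an order of magnitude more
than the degree-12 fit requires.

## Known limitations

* Lateral (frontal-plane) arm raises are invisible to the sagittal-plane
  elevation convention and degenerate at 90° abduction; the scripted
  shoulder movements are therefore frontal raises.
* An interruption falling *inside* a movement segment tears its content
  into two differently shifted halves; the per-segment model assigns one
  shift and leaves a residual within the segment (the paper's per-segment
  approach shares this property).
* The azimuth's neutral offset is unobservable in principle; azimuth
  accuracy near zero elevation is limited by the `min_projection` flagging
  rather than by the pipeline.
* Clock drift (rate error) is out of scope; only piecewise-constant
  offsets are modeled and corrected.
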