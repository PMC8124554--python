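# kinagree

Joint-angle agreement between a low-cost VR-tracker skeleton stream and a
marker-based optical reference stream.

Consumer VR hardware (head-mounted display, hand controllers, a few body
trackers) plus an inverse-kinematics solver yields full-body kinematics at
a fraction of the cost of a marker-based motion-capture system. Whether
those kinematics are accurate *enough for ergonomic risk assessment* —
where schemes like RULA and REBA score postures from joint-angle threshold
bands — is a question about sample-wise joint-angle error. `kinagree`
implements the full comparison pipeline for paired recordings of the same
subject: 16 joint angles are derived from each stream (body-plane
referenced angles, three-point flexion via the law of cosines, quaternion
relative rotation for the head), the streams are re-referenced, resampled
(90 → 100 Hz), low-pass filtered (2nd-order Butterworth, 3 Hz,
zero-phase), neutral-zero offset corrected, resynchronized globally from a
T-pose preamble and per movement segment with a coarse DTW pass
(0.5–2 s shifts) and a fine FFT pass (< 0.5 s), and corrected for
systematic angle-dependent deviations by a degree-12 polynomial regression
of the difference on the VR angle value.

Agreement is then summarized per angle by

* the 5–95% inter-percentile range (IPR) of the sample-wise differences,
  banded into good (±10°), medium (±15°) and poor;
* Lin's concordance correlation coefficient
  `ccc = 2σ_qv / ((μ_q − μ_v)² + σ_q² + σ_v²)` with McBride bands;
* modified Bland–Altman statistics (mean ± 1.96 SD limits of agreement,
  reference angle on the x-axis).

Because no real paired recordings are distributed, the package ships a
first-class synthetic-session generator: a scripted 20-movement protocol
with a T-pose synchronization preamble is posed by forward kinematics, and
a degradation model injects — with recorded ground truth — sample-rate
mismatch, recording interruptions that shift the VR clock, neutral
offsets, a shared smooth systematic distortion g(θ), band-limited noise,
tracker jumps and rigid-limb episodes. Every recovery claim in the test
suite is checked against this ground truth. See `docs/methods.md` for the
full model description.

## Worked example

Simulate a 3-subject cohort with two injected recording interruptions
(0.8 s and 1.4 s), per-subject neutral offsets, a shared systematic
distortion and 1° noise, then run the full pipeline:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_resynchronize.py
python analysis/03_fit_correction.py
python analysis/04_agreement_report.py
```

which prints (abbreviated):

```
wrote 3 paired sessions to .../scratch/sessions
injected: shared distortion on 16 angles, per-subject neutral offsets,
  1.0 deg noise, interruptions after movements ['05', '11'] (2.2 s total)

resynchronized 3 subjects x 20 segments
informative segments: 45; max |shift error| = 0.009 s

fitted degree-12 corrections for 16 angles
injected distortion recovered within 0.629 deg RMS over the central 90% RoM

agreement over 3 subjects, 69399 pooled linked samples
  neck_flex              IPR [  -1.34,   1.40] good   CCC  0.999 (almost_perfect)
  shoulder_left_elev     IPR [  -1.37,   1.39] good   CCC  1.000 (almost_perfect)
  elbow_left_flex        IPR [  -1.19,   0.99] good   CCC  1.000 (almost_perfect)
  knee_left_flex         IPR [  -1.10,   1.15] good   CCC  1.000 (almost_perfect)
  ...
```

Reading: the injected clock shifts (up to 2.2 s cumulative) are recovered
to within 9 ms; the injected systematic distortion is recovered to within
0.63° RMS; and after correction every angle's difference distribution is
within ±2° (class *good*), i.e. the residual error is dominated by the 1°
injected noise. Tables land under `results/`, the (large) session TSVs
under `scratch/`.

The same pipeline is available as a CLI for file-based use:

```sh
kinagree generate --out session/ --seed 7 --start-delay 0.3
kinagree compare --session session/ --out report/ --seed 7
```

`report/report.tsv` then holds one row per angle with IPR, class, CCC,
band and Bland–Altman columns; `report/sync.tsv` the per-segment shifts;
`report/corrections.json` the fitted correction polynomials. All outputs
embed the configuration hash and seed, and reruns are bit-identical.

## Layout

```
src/kinagree/      the library: skeleton/core types, io, angles,
                   preprocess, sync, correct, stats, synth, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             unit, property and end-to-end acceptance tests
scripts/           acceptance recomputation
docs/methods.md    model, conventions, generator scope, limitations
```
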