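# Methods

## Scope and data model

The package analyses sequences of 2-D interface-pressure frames from a
body–mattress sensing array. The native instrument modelled throughout is
a 118 × 48 grid (5664 sensors) at 15.9 mm pitch sampling at 1 Hz, with a
5–200 mmHg reporting range and ±2 mmHg accuracy. Readings below the range
floor are unreported and stored as 0; readings above the ceiling saturate
at 200 mmHg. The row axis is longitudinal (head to foot), the column axis
transverse, and cell (i, j) has its physical center at
((i + 0.5)·pitch, (j + 0.5)·pitch) mm. Sequences carry ground truth: a
posture label per frame (supine / lateral / high_sitting, or `transition`
during a movement) and the continuous-time instants of postural-change
events.

On disk a sequence is a directory of plain-text files: a sparse
long-format CSV of nonzero cells (`time_s,row,col,pressure_mmHg`), a JSON
metadata sidecar (shape, pitch, frequency, range, mattress, subject), and
labels/events CSVs. Floats are written with 17 significant digits and
parsed with correctly-rounded conversion, so write → read is bit-exact.

## Synthetic cohorts

No public recordings exist for this task, so cohorts are simulated. The
generator is deliberately the simplest model that produces the
statistical structure the pipeline measures; its defaults are the study
conditions for every result the tests and the acceptance script report.

**Body.** Six landmarks (head, two scapulae, sacrum, two heels), each an
isotropic 2-D Gaussian pressure bump with a longitudinal position
(fraction of body length), a transverse offset from the midline (mm), a
load weight and a spread (sigma, mm). A landmark's noise-free peak is
`total_load × weight` mmHg; the default body (length 1720 mm, total_load
30) gives a sacral peak of ~66 mmHg supine on foam, with scapular peaks
~36 and heel peaks ~15 mmHg — representative of adult supine lying on a
non-powered surface.

**Postures.** A posture is a per-landmark translation and re-weighting.
High sitting (head of bed raised) slides the cranial landmarks caudally
and shifts load onto the sacral region (sacrum weight × 1.6, cranial
weights × 0.5), moving the longitudinal COP by ~240 mm. Lateral lying
shifts the whole body 20 % of the mat width to one side, loads that
side's landmarks (× 1.3) while unloading the other (× 0.3), and narrows
every bump (spread × 0.85), shrinking the contact area by roughly a
third. These magnitudes are module-level constants and were chosen so
that every posture pair differs by more than two sensor pitches of
longitudinal COP or more than 10 % of contact area — the separability
that makes the downstream tasks well-posed (and that the test-suite
asserts). The two lateral sides are exact mirrors; both carry the ground
truth label `lateral`.

**Immersion.** A mattress regime is two scalars applied to every bump:
foam = (spread × 1.0, peak × 1.0); air = (spread × 1.4, peak × 0.8).
More immersion spreads load over a larger area with lower peaks. The air
values were chosen analytically so that the 20 mmHg contact area is
robustly larger on air than foam for the default body: with stronger
attenuation (e.g. × 0.7) the comparison degenerates because secondary
landmarks fall below the 20 mmHg threshold entirely.

**Protocol and transitions.** The default script is supine → high
sitting → supine → lateral, 60 s per segment, with 5 s transitions.
During a transition the two static fields are linearly cross-faded, and a
transient push-off bump is added: a sharp Gaussian (sigma 30 mm, offset
150 mm from the midline at hip level) whose amplitude follows
`artifact_weight × total_load × sin(π·w)` across the fade (default
weight 2.5, per-subject 2.0–3.0). This models the brief load
concentration of repositioning (pushing off with an arm or hip) and is
the mechanism that makes fast sampling genuinely more informative than
slow sampling: a 1 Hz sampler sees the movement itself, while a 0.1 Hz
sampler sees only the net before/after change. Without it, decimation
*concentrates* a posture change into one large difference and can raise
AUC at low frequencies for weakly-informative parameters — the opposite
of how real recordings behave. Setting `artifact_weight=0` restores the
pure cross-fade. The ground-truth event time is the fade midpoint.

**Noise and cohorts.** I.i.d. Gaussian noise (sd 2 mmHg, the stated
sensor accuracy) is added to the physical field before the reporting
rule. Cohort members vary in stature (length ~ N(1720, 80) mm,
truncated), load scale (~ N(30, 5), truncated), landmark transverse
jitter (±10 mm) and push-off vigor; every subject performs the same
script. Everything is reproducible bit-for-bit from one integer seed.

**What the generator does not emulate.** Real pressure images have
non-Gaussian fine structure (bony prominences, creases, clothing),
spatially correlated and non-stationary noise, air-cell inflation cycles,
and movements that are neither synchronous nor smooth. Consequently,
passing results here demonstrate that the *pipeline* is correct and that
its qualitative trends follow from the modelled mechanisms — not that a
particular AUC or accuracy level will be attained on real patients.
Synthetic postures are far more separable than real ones, so
classification accuracies near 100 % say nothing about clinical
performance.

## Down-sampling

Spatial: non-overlapping k × k block means, output cell (I, J) averaging
input rows [I·k, (I+1)·k) and columns [J·k, (J+1)·k); trailing rows and
columns short of a full block are discarded — forced by the pooled grid
sizes (118/5 → 23, 48/5 → 9). Pooled pitch is k × the input pitch, and
pooled values are *not* re-floored: a block mean may legitimately fall
below the 5 mmHg sensor floor, so pooled frames carry a flag relaxing
that invariant. Temporal: keep frames 0, n, 2n, … (first-sample
anchoring), dividing the frequency by n. 1/3 Hz is kept exact internally
and reported with the conventional label "0.3". Ground-truth event times
are continuous-time and pass through decimation unchanged.

## Pressure parameters

Seven per frame: COP (pressure-weighted centroid of cell centers, mm,
longitudinal and transverse), contact area at thresholds 5/10/20 mmHg
(inclusive ≥, reported as physical area in cm² = count × (pitch/10)² so
values are comparable across resolutions; raw counts available), peak
pressure (mmHg), and peak pressure gradient — the maximum |Δp| over
4-neighbour (edge-sharing) adjacent cell pairs, in mmHg per cell step.
Diagonal adjacency and per-mm normalization (divide by pitch) are
available as options but not defaults: the conventional definition never
divides by distance, and the per-cell-step form is what produces the
gradient's characteristic spatial trend (coarser cells → larger per-step
differences). COP of an all-zero frame is undefined and becomes a missing
value (NaN), never a silent zero.

## Event discrimination

The score for "a movement happened here" is the absolute per-sample first
difference of a parameter series, stamped at the midpoint of its sample
pair. Differences are per sample, not per second: a per-second derivative
would mechanically inflate low-frequency magnitudes and distort the
frequency comparison. Missing parameter values propagate into adjacent
differences and are dropped (pairwise) before scoring.

Samples within `tolerance` seconds of a true event are positive. The
default tolerance is `max(2.5 s, one sample interval)`: 2.5 s is half the
default transition duration, so at the native rate the positive window
covers exactly the samples whose differences straddle the movement, and
at decimated rates it widens to one inter-sample gap. A wider window
would label noise-only differences positive and cap the attainable AUC
regardless of the parameter's quality.

AUC uses the tie-aware Mann–Whitney formulation (ties at half weight),
computed from average ranks; the ROC curve is the threshold sweep over
distinct scores. Cohort results pool derivative samples and labels across
subjects and compute one grand AUC per configuration cell (a single value
per cell, as a summary table requires), rather than averaging per-subject
AUCs.

## Posture classification

Static (non-transition) frames are converted to 8-bit grey-scale with the
fixed full-range mapping `round(255·p/200)` (rounding half up). The fixed
range — not the per-frame maximum — preserves absolute pressure magnitude
across images, which carries posture information. The classifier is a
compact convolutional network implemented in numpy with explicit
forward/backward passes: 3×3 valid convolution (8 channels), ReLU, 2×2
max-pool, a 32-unit dense layer, softmax over the three postures, trained
with Adam (lr 1e-3, batch 32, default 20 epochs, 10 in the bundled
runs) on cross-entropy. The explicit implementation keeps training
bit-reproducible from a seed (fixed init and batch order) and lets the
test-suite verify every gradient numerically. Hyperparameters are
defaults of this package, not claims about any other system. The 80/20
split is drawn within each subject, stratified by posture (every subject
contributes to both splits); a leave-subjects-out mode exists but is not
the default. The reported figure is total accuracy on the held-out 20 %.

## Numerical choices and edge cases

- Sensor rule order in simulation: blend/artifact → noise → floor/ceiling.
- Pooling k = 1 and decimation n = 1 return the input unchanged.
- Decimation drops a ground-truth event only if it falls beyond the last
  kept frame's time (it can no longer be expressed within the sequence
  span); the default protocol never triggers this.
- `label_samples` errors on an empty event list or an event outside the
  recorded span; AUC errors on single-class labels and on non-finite
  scores (callers drop missing values first).
- Images smaller than the pooling window skip pooling; the network
  accepts any input at least as large as its kernel.
- CSV output is deterministic (fixed column order, LF endings, 17
  significant digits), so identical configurations produce byte-identical
  files.

## Problem sizes in the bundled runs

Test-suite and acceptance-script cohorts are deliberately desk-scale,
chosen as the smallest sizes at which the measured quantities are stable:
10 subjects × 255 frames for event discrimination (10 cohort seeds for
the frequency-monotonicity check), 5 subjects with one 20 s segment per
posture (300 class-balanced images) for classification, with 10 training
epochs. The full-cohort presets (20–27 subjects, 60 s segments, 20
epochs) are available through `RunConfig`.

## Known limitations

- The Gaussian-bump body has no biomechanics: no tissue deformation, no
  mattress memory, no anthropometric covariance between landmarks.
- The push-off artifact is a single fixed-position bump; real movement
  transients vary in place, number and duration.
- The positive/negative construction (tolerance windowing) is one of
  several defensible choices for turning event instants into per-sample
  labels; it is exposed as a parameter everywhere it is used.
- A grand pooled AUC weights subjects by their sample counts; with
  equal-length scripts this equals equal weighting, but mixed-length
  cohorts would need per-subject averaging (not implemented as default).
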