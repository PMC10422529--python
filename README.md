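# ipmap

Sensitivity analysis of body–mattress interface-pressure arrays to spatial
and temporal down-sampling.

## The problem

Commercial pressure-sensing mats used for pressure-ulcer risk monitoring
are high-resolution instruments — thousands of sensors sampling at 1 Hz or
more — yet much of that data is redundant for the two questions that
matter clinically: *when did the person move* (mobility), and *what
posture are they in* (repositioning adherence). If a far cheaper array
sampling far more slowly answers both questions equally well, monitoring
becomes viable outside specialist settings.

`ipmap` implements that sensitivity analysis as a tested, reusable
pipeline for a 118 × 48 array (15.9 mm pitch, 5–200 mmHg range, ±2 mmHg
accuracy, 1 Hz). It is aimed at researchers in pressure-injury prevention
and sensor design who want to rerun the analysis on their own recordings
or on simulated cohorts. Since no public recordings of this kind exist,
the package includes a first-class synthetic-data generator whose cohorts
carry full ground truth (per-frame posture labels and event times).

## The method

The pipeline has five stages:

1. **Simulate** (or load) labelled pressure-frame sequences. A body is a
   set of weighted landmarks (head, scapulae, sacrum, heels) rendered as
   Gaussian pressure bumps; postures re-weight and translate the
   landmarks; a mattress's immersion (foam vs. air) scales bump spread
   and peak. Postural transitions cross-fade between static renders with
   a transient push-off pressure artifact peaking at the event midpoint.
2. **Down-sample**: block-pool *k* × *k* sensor regions into their mean
   (k ∈ {1,2,3,4,5} → 5664, 1416, 624, 348, 207 sensors) and decimate to
   one frame every *n* seconds (n ∈ {1,2,3,5,10} → 1, 0.5, 0.3, 0.2,
   0.1 Hz) — a 5 × 5 grid of 25 configurations.
3. **Extract parameters** per frame: center of pressure (COP) along the
   longitudinal and transverse axes, contact area at the 5/10/20 mmHg
   thresholds, peak pressure, and peak pressure gradient (largest
   pressure difference between adjacent cells).
4. **Score event discrimination**: the absolute first difference
   |x[t+1] − x[t]| of each parameter series is a movement score; samples
   within a tolerance window of a true event are positives; the tie-aware
   Mann–Whitney AUC,

   AUC = (#{score⁺ > score⁻} + ½·#ties) / (n⁺ · n⁻),

   is computed per parameter per configuration, pooled over the cohort.
5. **Classify postures**: static frames become 8-bit grey-scale images
   (intensity = round(255·p/200), fixed full-range mapping) and a small
   convolutional network (3×3 conv, ReLU, 2×2 max-pool, dense, softmax)
   is trained per spatial resolution on an 80/20 within-subject split,
   reporting total accuracy.

## A worked example

```python
from ipmap import make_cohort, roc_auc, scores_and_labels
import numpy as np

cohort = make_cohort(5, regime="air", seed=3, noise_sd=2.0)
for block, decim, label in [(1, 1, "5664 @ 1 Hz"), (1, 10, "5664 @ 0.1 Hz"),
                            (5, 1, "207 @ 1 Hz")]:
    pooled = {}
    for seq in cohort:
        for name, (s, l) in scores_and_labels(seq, block, decim).items():
            pooled.setdefault(name, [[], []])
            pooled[name][0].append(s); pooled[name][1].append(l)
    a = {n: roc_auc(np.concatenate(s), np.concatenate(l)).auc
         for n, (s, l) in pooled.items()}
    print(label, round(a["cop_long"], 3), round(a["contact_area_20"], 3),
          round(a["peak_gradient"], 3))
```

prints (columns: longitudinal COP, contact area ≥ 20 mmHg, peak gradient):

```
5664 @ 1 Hz 0.97 0.919 0.63
5664 @ 0.1 Hz 0.724 0.735 0.43
207 @ 1 Hz 0.973 0.786 0.949
```

Slowing the sampler to 0.1 Hz costs every parameter discrimination,
because the movement transient falls between samples. Coarsening the
grid barely affects the COP, hurts contact area, and *helps* the peak
gradient — the two opposing spatial trends the analysis is designed to
expose. The scripts in `examples/` walk through each capability
(simulation, down-sampling, parameter extraction, ROC scoring,
classification, and the full run); `ipmap --help` exposes the same stages
as a command line.

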