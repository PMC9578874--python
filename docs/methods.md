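# Methods

`fatiguekit` implements a bimodal fatigue detector for settings such as
air-traffic-control workstations, where short face-video and speech clips
are recorded continuously. The method has three stages: (1) per-frame eye
and mouth open/closed classification producing binary closure-state
queues, (2) clip-level feature extraction — five temporal facial features
from the queues and an MFCC matrix from the paired audio — and (3) a
two-layer stacked ensemble that fuses both modalities into one fatigue
probability. This note records the model, its assumptions, the defaults
and the deliberate design choices.

## Closure-state queues and temporal facial features

A queue is a fixed-fps binary sequence, one flag per video frame, with
1 = open and 0 = closed. The five clip-level features are

* **blinks** — the number of maximal closed runs in the eye queue. A
  closed run touching the clip boundary counts as a blink: this is the
  simplest rule that never discards observed closure, at the cost of
  occasionally counting a truncated half-blink.
* **ABT** (average blinking time) — total closed frames divided by the
  blink count, divided by fps. Reported in seconds so the feature is
  comparable across frame rates.
* **ABTI** (average blink time interval) — the open frames strictly
  between the first and last closed run, divided by (blinks − 1), in
  seconds. Leading and trailing open stretches are not intervals between
  blinks and are excluded.
* **PERCLOS** — fraction of frames with eyes closed; the classic
  drowsiness proxy.
* **FOM** (frequency of open mouth) — fraction of frames with the mouth
  open, a yawn proxy. Some formulations define the closed-mouth
  complement; that dialect is available as
  `fom_convention="closed_fraction_as_printed"`, but the default follows
  the yawn semantics, since mouth *opening* is what correlates with
  fatigue.

Degenerate denominators (no blink for ABT, fewer than two blinks for
ABTI) return 0 and set a flag in the feature vector's metadata rather
than producing NaNs; the flags let downstream consumers distinguish "no
blinks" from "instantaneous blinks".

## Region geometry

Eye and mouth patches are cropped from 68-point facial landmarks (the
standard 0-based annotation: 36–41 left eye, 42–47 right eye, 48–59 outer
lip). The box width is 1.2× the feature's horizontal landmark span — the
20% margin keeps the full eyelid/lip in view — and the height follows the
classifier input aspect: eye patches are 34 px wide × 26 px high, mouth
patches 120 × 80. Boxes are centred on the feature's landmark centroid,
making them equivariant under translation and uniform scaling. Crops are
clipped to the image, bilinearly resized to the classifier shape and
rescaled to [0, 1]. Landmark estimation itself is a pluggable upstream
step; the core never downloads or bundles a detector. Both eyes are
cropped by default and a frame counts as eyes-closed only if both sides
classify closed (single-eye mode is available), which suppresses winks
and unilateral landmark glitches.

## Closure classifiers

E-CNN (eye) and M-CNN (mouth) are small binary CNNs: three 3×3
convolution blocks with 2×2 max pooling, two fully connected layers and a
sigmoid output. Filter counts are 8/16/32 with dense widths 64/32 —
deliberately the smallest stack that saturates accuracy on patches with
clear open/closed geometry; the classification task (dark aperture
present vs absent) does not benefit from wider layers, and small nets
train quickly on a single CPU. Training uses Adam (1e-3), binary
cross-entropy and a seeded 80/20 held-out split. The decision threshold
on p(open) defaults to 0.5. The networks are implemented on a small
in-package NumPy layer library with manual backpropagation (`fatiguekit.nn`),
gradient-checked against finite differences in the test suite.

## MFCC chain

The voice features are classic static MFCCs: pre-emphasis
(α = 0.97), 512-sample frames with 256-sample hop, Hamming window, 512-point
DFT power spectrum, 26 triangular mel filters spanning 0 Hz–Nyquist,
log with a 1e-10 floor, orthonormal DCT-II, first 20 coefficients.
At 16 kHz and 7 s of audio this yields a 20 × 436 matrix. Delta and
delta-delta features (±2-frame regression window) are available but off
by default, since static coefficients suffice for clip-level class
separation. Two mel-scale dialects are provided: the standard
2595·log10(1 + f/700) (default) and an alternative printed
parameterisation 2569·log10(1 + f/100) kept for reproducibility of
sources that use those constants; both are monotone with mel(0) = 0. The
tests validate the chain against an independent reference written from
explicit DFT/DCT matrices and explicit triangle formulas.

## Stacked ensemble

Five base learners: logistic regression, CART (Gini, unlimited depth),
and a linear SVM (C = 1, probabilities via a logistic link fitted on the
training margins) on the z-scored 5-vector of facial features; an LSTM
(hidden size 32, final hidden state → sigmoid) and a CNN
(three conv/pool blocks, one dense layer) on the per-coefficient
standardised MFCC matrix. The LSTM consumes the frame sequence with a
fixed stride of 4 (436 → 109 steps), which halves-twice the
backprop-through-time cost with no measurable accuracy loss on clip-level
classification; the CNN treats the matrix as a 1-channel image.

The meta-learner is a logistic regression over the five base
probabilities. Its training inputs are built with stratified 5-fold
out-of-fold stacking: each base learner is trained k times on k−1 folds
and scores only the fold it never saw, so the meta-learner's n × 5 input
matrix contains no leaked probability. The fold bookkeeping is retained
in the results object and `verify_no_leakage()` re-checks it. After the
out-of-fold pass, the base learners are refitted on all training data for
deployment. Base outputs are probabilities, not hard labels — they
preserve the learners' confidence. Scaling statistics (facial z-score,
per-coefficient MFCC standardisation) are computed once on the full
training set: the scaler is a fixed affine map applied identically at
training and deployment, which keeps the deployed model self-contained;
fold-local scaling would be marginally stricter but complicates
deployment for no observed benefit on these features. The decision
threshold is 0.5.

The ensemble is exposed statsmodels-style: `FVStackingModel(facial,
voice, labels)` (or `from_corpus` / `from_dataframe`) with `.fit(k_folds,
seed)` returning a `StackingResults` that carries the fitted learners,
out-of-fold matrix, fold assignments, meta coefficients, `predict()` and
`summary()`.

## Evaluation

Recall, precision, accuracy and F1 come from the standard confusion
counts with 1 = fatigued as the positive class; 0/0 cases return 0 with a
flag. The ROC curve sweeps thresholds over the unique scores, grouping
ties into single steps, and the AUC is the trapezoidal area — verified in
the tests to equal the pairwise concordance probability
P(s⁺ > s⁻) + ½P(tie) to 1e-12. A feature-subset baseline harness
evaluates LR/SVM/KNN on subsets of the facial features (e.g.
{PERCLOS, blinks}, {PERCLOS, FOM}) against the full fusion model on a
shared train/test split, mirroring threshold-based detectors from the
drowsiness literature.

## Synthetic study conditions

Real paired face/voice fatigue corpora are rarely shareable, so the
generator defines reproducible study conditions; the sampling class *is*
the ground-truth label.

| parameter | alert | fatigued | unit |
|---|---|---|---|
| blink rate | 15 | 24 | events/min |
| blink duration (mean ± sd) | 0.15 ± 0.05 | 0.45 ± 0.15 | s |
| yawn rate | 0.2 | 2.0 | events/min |
| yawn duration (mean ± sd) | 4 ± 1 | 5 ± 1.2 | s |
| voice fundamental f0 | 160 | 110 | Hz |
| syllable rate (AM) | 5.0 | 2.5 | Hz |

Clips are 15 s of video at 25 fps and 7 s of audio at 16 kHz. Blink and
yawn parameters are in the range of the ocular-fatigue literature (alert
adults blink ~10–20/min for ~0.1–0.3 s; drowsiness lengthens and
multiplies closures); the audio emulates lowered pitch and slowed speech
rhythm under fatigue with a 5-harmonic carrier, syllable-rate amplitude
modulation and additive white noise (σ = 0.05 before peak
normalisation). Event counts are Poisson at the class rate; event
durations are truncated normal (minimum one frame); events are placed
uniformly without overlap, and events running past the clip end are
truncated with a logged warning. Everything is a pure function of
(params, seed).

Patches are rendered geometrically: open eyes are a bright sclera
ellipse with a dark pupil disc, closed eyes a thin lash arc; open mouths
a tall dark aperture with a lip ring, closed mouths a thin lip line —
with jittered centres/axes and additive noise.

What the generator does **not** emulate: photorealistic appearance,
landmark-estimation noise, head pose, illumination changes, phonetic
content, speaker identity, or label noise — real corpora are harder on
every axis. Passing tests therefore demonstrate correctness of the
pipeline and the expected *qualitative* behaviours (fusion ≥ best single
model, multimodal > facial-only), not field-ready detection accuracy.

## Problem sizes and numerics

The shipped checks use sizes that exercise every component at meaningful
statistical scale while staying desk-friendly: 2,000 patches per closure
classifier (5 epochs), a 2,000-clip corpus with a 75/25 split and 5-fold
stacking, 1,000 random queues for the feature oracle, 100 score sets for
the AUC cross-check. Networks run in float32; spectral code in float64.
Log energies are floored at 1e-10 before the log. Max-pool ties break to
the first element; pooling truncates odd trailing rows/columns.

## Known limitations

* The generator's class separation is intentionally strong; accuracy
  numbers on synthetic corpora are upper bounds, not estimates of
  real-world performance.
* The LSTM/CNN voice learners are small and CPU-oriented; they are not
  speech models and would need replacing for noisy multi-speaker audio.
* ABTI excludes boundary open runs, which differs from definitions that
  average all open runs; both reduce to the same value for interior
  blinks.
* No calibration of the fused probability is performed beyond the
  logistic meta-fit.
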