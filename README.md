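# fatiguekit

Bimodal fatigue detection from short face-video and speech clips, aimed
at monitoring scenarios such as air-traffic-control workstations. The
toolkit fuses **facial blink/yawn dynamics** with **voice cepstral
features** in a two-layer stacked ensemble and ships a synthetic-data
generator so the entire pipeline can be trained and tested without
access to confidential recordings.

## The method

1. **Closure-state queues.** Two small CNNs (E-CNN for 26×34 eye patches,
   M-CNN for 80×120 mouth patches; three conv+pool blocks, two dense
   layers, sigmoid) classify each video frame as open/closed, producing a
   binary queue per channel (1 = open, 0 = closed). Patches are cropped
   from 68-point facial landmarks: box width is 1.2× the feature's
   horizontal span, height follows the patch aspect ratio.
2. **Five facial features per clip** from the queues: blink count,
   average blinking time ABT = (n_close/N_blinks)/fps, average blink
   interval ABTI, PERCLOS = n_close/N_total, and FOM (open-mouth frame
   fraction, a yawn proxy).
3. **Voice features**: static MFCCs via the classic chain — pre-emphasis
   (α=0.97), framing (512/256 at 16 kHz), Hamming window, DFT power
   spectrum, 26 triangular mel filters (mel(f) = 2595·log₁₀(1+f/700)),
   log, orthonormal DCT-II, 20 coefficients. A 7 s clip yields a 20×436
   matrix.
4. **FV-Stacking**: five base learners — LR, CART and linear SVM on the
   standardized facial features; an LSTM and a CNN on the standardized
   MFCC matrix — feed a logistic-regression meta-learner trained on
   stratified **out-of-fold** probabilities, so no meta-training input
   ever comes from a learner that saw that clip.

Evaluation uses recall, precision, accuracy, F1 and a tie-aware
trapezoidal ROC/AUC, plus a feature-subset baseline harness (LR/SVM/KNN
on facial-feature subsets) for comparison against threshold-style
detectors.

## Worked example

```python
import numpy as np
from fatiguekit import gen_corpus
from fatiguekit.stacking import FVStackingModel, corpus_to_arrays

clips, manifest = gen_corpus(200, class_balance=0.5, seed=0)
facial, voice, labels, ids = corpus_to_arrays(clips)

results = FVStackingModel(facial[:150], voice[:150], labels[:150]).fit(
    k_folds=5, seed=0
)
results.verify_no_leakage()
print(results.summary())

probs, preds = results.predict(facial[150:], voice[150:])
print(f"held-out accuracy on 50 clips: {(preds == labels[150:]).mean():.3f}")
```

prints

```
FV-Stacking results
===================
n samples: 150   folds: 5   seed: 0

Base learners (out-of-fold accuracy / meta weight):
  lr           0.987     +1.372
  cart         0.993     +1.527
  linear_svm   0.993     +1.552
  lstm         1.000     +1.639
  cnn          1.000     +1.917
  intercept              -3.837

held-out accuracy on 50 clips: 1.000
```

The first column is each base learner's out-of-fold accuracy on the
training corpus; the second is its weight in the logistic meta-learner —
all positive here, meaning every modality contributes to the fused
decision. On synthetic corpora the classes are well separated by design,
so absolute accuracies are upper bounds, not field estimates (see
`docs/methods.md`).

The same flow is available from a shell:

```bash
fatiguekit simulate --n 200 --seed 0 --out corpus/
fatiguekit end-to-end --corpus corpus/ --out run/ --seed 0
fatiguekit baselines --corpus corpus/ --seed 0 --out baselines.csv
```

`run/` then holds `predictions.csv`, `metrics.json` (both stamped with
the config hash and seed) and the pickled fitted model.

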