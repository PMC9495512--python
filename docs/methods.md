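# Methods

This note documents the models, algorithms and numerical choices behind the
package: a multiscale residual 1D-CNN ("MsRes"-style encoder) for binary
atrial-fibrillation (AF) detection on short single-lead ECG segments, plus
the synthetic data, balancing and evaluation machinery around it.

## The detection problem

A single-lead ECG at 300 Hz is cut into fixed 9 s windows (2,700 samples)
and each window is classified AF vs non-AF. The two class-defining cues on
a single lead are (i) the irregularity of the RR intervals — the times
between successive ventricular beats — and (ii) the replacement of the
atrial P wave by a continuous low-amplitude fibrillatory oscillation
("f-waves", clinically cited in the 4–10 Hz band). The encoder learns both
cues directly from the raw, per-segment min-max-normalized waveform; no
filtering, resampling or feature engineering is applied.

## Architecture

The network is a set of parallel streams, one per *scale*. A stream with
stem kernel width `k` computes:

1. **Stem convolution** — 1 input channel → 32 filters, kernel `k`, stride
   3, valid padding, no activation. Output length `floor((2700 − k)/3) + 1`.
2. **Seven residual blocks** — each block is
   `y = maxpool(relu(conv2(relu(conv1(x)))) + x)` with two same-padded
   kernel-3, 32-filter convolutions (3,104 parameters each) and a valid
   max-pool of size 5, stride 2. The identity shortcut requires the convs
   to preserve shape, which fixes their padding and stride.
3. The pooled output of the last block has length 4 for every kernel in
   {3, …, 13}, so each stream flattens to 4 × 32 = 128 features.

Stream features are concatenated (384 for three streams) and fed through a
dense head 64 → 32 → 16 (ReLU, dropout 0.25 after the first two) into a
single sigmoid unit. Parameter accounting is exact and closed-form at the
default geometry:

```
total = 32·Σk_i + 51,680·n_streams + 2,689
```

giving 158,401 for kernels {5, 7, 9}. The symbolic ledger
(`msres.model.config`) and the executable network (`msres.model.network`)
are verified against each other in the tests.

Batch normalization is deliberately absent: the reference layer ledger
lists no BN parameters. The dense-head hidden activations are ReLU (the
ledger does not name them; ReLU is the field default and does not affect
any parameter count).

### Numerical implementation

The trainable network is written in numpy with hand-derived gradients,
checked against central finite differences to ~1e-6 relative error
(float64). Two implementation choices matter for CPU speed:

* same-padded kernel-3 convolutions are evaluated as three shifted
  GEMMs over the batch flattened to one long signal, accumulated in place
  through BLAS (`sgemm`/`dgemm` with transpose tricks so no operand is
  ever copied); the few rows whose shifted source crosses a segment
  boundary are corrected afterwards;
* max-pool argmax/scatter and the ReLU backward mask are numba-JIT
  kernels (pure-numpy fallbacks are used if numba is unavailable).

Weights are Glorot-uniform with an explicit seed; training is bitwise
reproducible for a fixed seed on a fixed BLAS. Classification threshold is
0.5 on the sigmoid output.

## Training protocol

Adam (lr 0.001, β = 0.9/0.999), batch size 128, binary cross-entropy with
probabilities clipped to [1e-7, 1 − 1e-7], 50 epochs by default, seeded
epoch-level shuffling, trailing short batches kept. Adadelta and Adagrad
are available for comparison. Evaluation is stratified 5-fold
cross-validation (each fold held out once; fold sizes and per-fold class
counts within one of each other); a single stratified 8:2 hold-out split
is also provided. An optional validation split (history only) mirrors the
usual training-curve diagnostics.

## Class balancing

The training data are heavily imbalanced (the emulated archive has 771 AF
vs 7,757 non-AF records). Three from-scratch oversamplers operate on the
flattened 2,700-dimensional segments under Euclidean distance, all with
k = 5 neighbors and `sampling_strategy = 1` (equalize classes) by default:

* **SMOTE** — synthetic point `x + u(x_nn − x)`, `u ~ U(0,1)`, `x_nn` one
  of the k nearest minority neighbors of a random minority seed.
* **Borderline-SMOTE** — seeds restricted to the DANGER set: minority
  points with at least k/2 but fewer than k majority points among their k
  nearest neighbors in the pooled data; empty DANGER set falls back to
  plain SMOTE with a warning.
* **ADASYN** — per-seed allocation proportional to the majority fraction
  of its neighborhood (largest-remainder rounding to hit the requested
  count exactly; uniform if every neighborhood is pure minority), plus
  Gaussian jitter. The jitter magnitude is not standardized anywhere, so
  it defaults to 0.01 × the per-feature minority standard deviation.

k-NN distance ties are broken by ascending sample index, which makes every
sampler deterministic under a fixed seed. By default balancing runs on
training folds only, so synthetic points never contaminate held-out data;
a `balance_first` switch applies balancing to the whole population before
splitting for comparability with protocols that do so (the leakage this
causes is the reason it is not the default).

## Synthetic ECG generator

No public generative model accompanies the detection task, so the package
ships the simplest generator that carries exactly the two diagnostic cues:

* **Beats** are sums of Gaussian bumps, one per P/Q/R/S/T deflection
  (defaults, as offset s / width s / amplitude mV relative to the R peak:
  P −0.20/0.025/0.15, Q −0.05/0.010/−0.10, R 0/0.012/1.20,
  S 0.04/0.010/−0.25, T 0.30/0.060/0.35). The P bump is omitted for AF.
* **Rhythm**: sinus RR = 60/HR × (1 + ε), ε ~ N(0, cv) with cv = 0.05 at
  70 bpm; AF RR is log-normal with matching mean and cv = 0.25 at 100 bpm
  (log-normality guarantees positivity and the right skew). Both are
  floored at 0.25 s, a ventricular refractory bound.
* **f-wave**: a 7 Hz, 0.08 mV sinusoid (inside the clinically cited 4–10
  Hz band) whose phase random-walks at 0.05 rad/sample and whose envelope
  wanders ±25 % with a 1 s AR(1) time constant — disorganized but
  band-limited, as fibrillatory activity is.
* **Noise**: additive white Gaussian, 0.05 mV SD.
* **Durations** are drawn uniformly from [9, 61] s, the archive's range;
  the archive's 771 : 7,757 imbalance is the default class ratio.

Records are bit-reproducible from a seed; per-record seeds derive from a
master seed via `SeedSequence`.

What the generator does **not** emulate: real electrode noise and motion
artifacts, baseline wander, morphology variation across subjects and lead
placements, non-AF arrhythmias ("other rhythms" collapse to normal
morphology, matching the binarized task), or ECGSYN-grade beat dynamics.
Consequently, passing the synthetic end-to-end tests demonstrates that the
pipeline is implemented correctly and can recover the AF cues it is built
around — not that the reported real-data accuracy transfers; real-archive
performance must be measured on the real archive.

## Preprocessing details and conventions

* Windows are half-open `[i·step, i·step + window)` with 0-based sample
  indexing; trailing partial windows are discarded (the fixed
  2,700-sample input forbids padding). The "step size of 9" is read as 9
  seconds: 27,108 segments from 8,528 records (~3.2 per record) is
  consistent only with a seconds-scale step.
* Start-clipping defaults to 0 s (no published clip length exists); it is
  exposed as a parameter.
* Min-max normalization maps a constant segment to all-zeros (the formula
  is undefined there and a constant segment carries no information).
* The stem convolution uses valid padding. The published stem lengths
  (900/899/898 for kernels 5/7/9) fit no single standard convention;
  valid padding reproduces 898 for kernel 9, and the choice provably does
  not alter any parameter count or the final per-stream length of 4. The
  first published pooling length (498 from 900) is arithmetically
  inconsistent with a valid pool(5, 2) — read as a typo for 448; all
  subsequent pooling rows match the valid formula exactly.

## Evaluation suite

Confusion counts, precision = TP/(TP+FP), recall = TP/(TP+FN), accuracy,
and F1 = 2PR/(P+R) are computed in exact arithmetic from integer counts; a
degenerate denominator reports 0 with a flag rather than raising, so fold
aggregation never aborts. PR and ROC curves sweep every unique score as a
threshold; ROC runs from (0, 0) to (1, 1) and the AUC is trapezoidal.
The suite is cross-checked in tests against brute-force enumeration and
scikit-learn.

## Known limitations

* Training the numpy network is CPU-bound; the shipped experiments use
  hundreds-to-thousands of segments and ~10 epochs, which this
  implementation handles in minutes. Archive-scale training (≈40k
  balanced segments × 50 epochs) is possible but slow.
* Single-lead, binary task only; no multi-class rhythm discrimination.
* The 8:2 segment-level split can place segments of one record on both
  sides of the boundary; `group_by_record=True` avoids this at the cost
  of only approximately exact split sizes.
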