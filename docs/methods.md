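# Methods

## Problem and model

`rtafnet` detects atrial fibrillation (AF) in fixed 10-second windows of
single-lead ECG (4000 samples at 400 Hz). AF shows two signatures a
classifier can exploit: the loss of organized atrial activity (no P wave,
replaced by low-amplitude fibrillatory "f" waves) and an irregularly
irregular ventricular response (high RR-interval variability). The first is
a local-morphology cue, the second a long-range temporal one, which
motivates the hybrid architecture:

* **Residual convolutional backbone.** A strided stem convolution (kernel
  15, stride 2, 64 channels) followed by four stages of two residual blocks
  each (channels 64/128/256/512, stage strides 2/2/2/1). A block is
  conv–BatchNorm–GELU–conv–BatchNorm plus a shortcut (identity, or a
  strided 1x1 projection with BatchNorm when shapes change), with GELU
  applied after the addition. Total temporal downsampling is 16, so a
  4000-sample window becomes a 250 x 512 feature sequence.
* **In-backbone attention.** Lightweight self-attention blocks
  (LayerNorm -> 4-head MHSA -> residual add) are appended to stages 2 and
  3, injecting medium-range context while the representation is still
  cheap.
* **Transformer encoder.** Sinusoidal positional encoding plus N = 3
  post-norm encoder layers (8 heads, feed-forward width 1474, ReLU inside
  the FFN, dropout 0.3) model rhythm irregularity across the whole window.
* **Multi-scale pooling fusion.** Global max pooling and global average
  pooling over time are concatenated into a 1024-vector (max captures
  prominent deflections, average the overall morphology background).
* **Classifier.** Two fully connected layers 1024 -> 256 -> 2 with ReLU and
  dropout, softmax on top.

This reference configuration totals 17,020,936 trainable parameters
(17.02 M). The published architecture pins the feature geometry (L' = 250,
D = 512, classifier 1024 -> 256 -> 2, attention in stages 2–3) and the
parameter total but not the encoder depth or FFN width; N = 3 with
ffn_dim = 1474 is the frozen choice that satisfies all of these constraints
simultaneously.

## Training algorithm

One training step samples a mini-batch through a weighted random sampler
(per-sample weight proportional to 1/N_class, so expected batch composition
is balanced), computes weighted cross-entropy (class weights
w_c = N_total / (n_classes x N_c), i.e. inverse class frequency), resets
gradients, backpropagates, clips the global gradient L2 norm to C = 1.0,
and applies AdamW. Both the weighted sampler and the weighted loss are
active together, as the training algorithm prescribes; their compensation
overlaps deliberately.

Learning rates are layer-wise: backbone at the base rate eta = 5e-4,
attention modules (in-backbone attention blocks and the encoder) at
1.5 eta, classifier head at 2.0 eta. The schedule is cosine annealing with
warm restarts (first cycle T0 = 10 epochs, cycle doubling, floor 1e-6),
stepped per epoch. Defaults: batch size 64, at most 150 epochs, early
stopping when the validation support-weighted F1 fails to improve for
P = 20 consecutive epochs (equality counts as non-improvement); the best
checkpoint (earliest argmax of validation F1) is restored on stop. AdamW
weight decay is 1e-4, excluded for biases and normalization parameters —
the decay value, SGDR cycle and head dropout are conventional choices the
source architecture leaves open.

The whole stack (layers with explicit forward/backward passes, AdamW,
SGDR, clipping, sampling) is implemented in NumPy. Gradients are exact and
are verified against central finite differences in the test suite. The
model computes in float32 for speed; the layer oracles and gradient checks
run in float64 through the layers' `dtype` argument. A BatchNorm layer
seeds its running statistics from the first training batch and then tracks
them with momentum 0.1, so evaluation mode is meaningful even after very
few optimizer steps (relevant for the desk-scale experiments below).

## Preprocessing

Lead II is selected when a record has multiple channels (configurable
fallback to channel 0); signals are resampled to 400 Hz by polyphase
band-limited interpolation; a fourth-order Butterworth band-pass
(0.5–45 Hz) is applied forward-backward (zero phase, effective order 8) to
the *whole record* before windowing, so the 0.5 Hz edge does not ring
inside every 10 s segment. Windows are non-overlapping, 4000 samples;
trailing remainders are dropped. Fine rhythm tags map to binary labels as
AF, AFL -> AF and N, J, NSR -> NonAF; "other"/"noisy" tags are excluded.
A window overlapping several rhythm intervals takes the tag with the
largest overlap duration, ties broken toward AF (screening sensitivity).
Splits are 70:15:15, stratified: at window level per label, or at record
level by greedily assigning whole records (largest first) within each
record-majority class so no record straddles splits.

Augmentation is applied only to AF windows of the training split: each
gains ratio - 1 copies (default ratio 2.0, doubling AF), each copy taking
Gaussian noise at 2% of the window SD *and then* one interior span of
2–10% of the samples replaced by linear interpolation. Composing both
operations on each copy is the reading consistent with a single ratio
producing a net doubling.

## Evaluation

AF is the positive class. Accuracy, per-class precision/recall/F1 from the
confusion matrix at the argmax (0.5) threshold, and support-weighted
averages — the convention under which weighted recall equals accuracy
identically and which uniquely reproduces the published benchmark tables
from their printed confusion matrices. AUC is the trapezoidal area under
the ROC curve, numerically identical to the pair-ranking statistic (ties
half-counted); 0/0 metric cells are defined as 0 and flagged. The
fine-grained error analysis tabulates predicted AF/NonAF per rhythm tag;
a row's error rate is its fraction in the *clinically* wrong column:
predicted NonAF for true AF, predicted AF for everything else — including
atrial flutter, which training folds into the AF label but which remains a
distinct arrhythmia, so AF calls on AFL windows are reported as confusions.
Cross-dataset transfer evaluates a trained model on another generator's
test windows with no fine-tuning, tagging the report with source/target
provenance.

## Synthetic data

The simulator generates what the classifier exploits, not full
electrophysiology. Beats are sums of five Gaussian kernels (defaults:
P 0.15 mV/40 ms at -160 ms, Q -0.10/15 at -40, R 1.0/25 at 0,
S -0.15/15 at +40, T 0.30/70 at +300 ms relative to the R peak).

* **NSR**: RR intervals from a clipped Gaussian (default 70 bpm, CV 0.03);
  P wave present.
* **AF**: i.i.d. Gamma RR intervals (default 95 bpm, CV 0.25) — serial
  irregularity without autonomic autocorrelation structure; no P wave; a
  6 Hz fibrillatory baseline of 0.08 mV with per-cycle amplitude/phase
  jitter.
* **AFL**: saw-tooth flutter baseline at 5 Hz (0.15 mV, with a second
  harmonic), RR = k x atrial cycle with k a random small integer
  (variable AV block).

Baseline wander (0.05 mV at 0.25 Hz) and white noise (0.03 mV SD) are
added from a noise RNG stream independent of the rhythm stream, both
spawned from the record seed, so noise settings never move beat times.
Records are annotated with rhythm intervals that tile their duration.

What the simulator does *not* emulate: respiratory modulation and
heart-rate turbulence, realistic QRS axis/morphology variation across
patients, muscle artifact and electrode motion, multi-lead projections,
and rhythm transitions within a record (each synthetic record is
single-rhythm, though the windowing/labeling path handles mixed records).
Passing tests therefore demonstrate that the implementation learns and
measures the intended signatures, not that the published real-data scores
transfer; those require the original clinical recordings.

A note on one simulator-derived check: the P-window discriminability
oracle measures mean squared amplitude 70–200 ms before each R peak,
restricted to beats whose preceding RR interval is at least 0.7 s — at
shorter cycles the previous beat's T wave enters the window and masks the
comparison (exactly as in real tracings at high ventricular rates). Under
the default amplitudes this statistic is about 2.4x larger for NSR than
for AF and ordered correctly in effectively every matched-seed pair.

## Desk-scale experiment sizes

The repository's experiments are sized for a single CPU. The end-to-end
check trains a scaled-down configuration (stem stride 4, two stages of
widths 32/64, D = 64, one encoder layer, four heads, ffn 128, classifier
hidden 64, L' = 125) on 400 synthetic windows per class (100 per class for
validation and test), reaching weighted F1 >= 0.95 within a few epochs.
The class-imbalance ablation trains an even smaller single-stage variant
(D = 32) on an 8:1 NSR:AF training set for three epochs, ten seeded
replicates, comparing minority-class recall with and without the weighted
loss. The reference 17 M-parameter configuration is instantiated and
forward-passed in the tests but trained only in scaled form.

## Numerical choices and degenerate inputs

Softmax and log-softmax are max-shifted for stability; non-finite logits
abort training with a diagnostic. Attention scaling is 1/sqrt(d_k).
Convolution padding is symmetric 'same'-style (output length ceil(L/s)).
The mask span in augmentation is interior, so interpolation endpoints
always exist; a constant window cannot be noise-augmented (SD undefined)
and is rejected. Empty classes make weighting/sampling/stratification fail
loudly. ROC analysis requires both classes. Ties in early stopping resolve
to the earliest best epoch; ties in window labeling resolve toward AF.
Seeds: every stochastic stage draws from a child of one master
`SeedSequence`, and per-record/per-copy streams are spawned, so any stage
can be re-run in isolation bit-identically.

## Known limitations

No variable-length input (windows are exactly 4000 samples); no multi-lead
fusion; no quality-based window rejection; the Transformer-only ablation
realizes "no convolution stages" as a single strided stem so the attention
budget stays fixed — a literal raw-sample Transformer would not fit the
L' contract. FLOP accounting uses the 1 MAC = 2 FLOPs convention and
counts convolutions, attention and linear layers (normalization and
activations are omitted as lower-order terms).
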