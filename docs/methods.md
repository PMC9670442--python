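# Methods

## Problem and model

`cardiov` estimates an ordinal *critical value* — 0 (no risk) < 1 (low
risk) < 2 (medium risk) < 3 (high risk) — from a 10-second, 12-lead,
500 Hz ECG. Two components carry the substance:

1. **Statement mapping.** Clinical ECG reads are sets of SCP-ECG statement
   codes (NORM, AF, IMI, ...). The packaged table assigns each of 71 codes
   one critical value; the partition is 3 / 28 / 26 / 14 codes for values
   0–3. A record is labeled with the **maximum** value over its statements.
   The maximum rule is the only aggregation under which every record gets
   exactly one value while benign co-annotations (e.g. "sinus rhythm")
   cannot mask a high-risk finding; it also explains why fewer records are
   labeled no-risk than carry a "normal ECG" statement. Statement
   likelihoods attached to codes (PTB-XL style) are ignored: any mentioned
   finding counts.

2. **Ordinal classifier.** A 1D convolutional network maps the waveform
   `X ∈ R^{12×n}` to three logits `z`. The four-level target is decomposed
   into three cumulative binary tasks (the Frank–Hall construction):
   `y_k = 1{value > k}` for k = 0, 1, 2, giving targets (0,0,0), (1,0,0),
   (1,1,0), (1,1,1). Training minimizes the mean binary cross-entropy of
   `p = sigmoid(z)` against `y` over the three tasks. Class probabilities
   are the consecutive differences

       q = (1 − p0,  p0 − p1,  p1 − p2,  p2),

   which sum to 1 for every `p ∈ [0,1]^3` and reproduce the four reference
   rows exactly. The prediction is `argmax q`, ties to the lower class.
   When the unconstrained sigmoids are non-monotone, middle entries of `q`
   can be negative; they are left as-is because a negative entry can never
   win the argmax, whereas clamping would silently change decisions. A
   non-normalizing "literal" variant of the middle differences (chaining
   through class rather than cumulative probabilities) is retained behind a
   flag purely for comparison; it assigns zero probability to a perfectly
   predicted low-risk record and is never used by the model.

## Architecture

Seven stages of pre-activation residual bottleneck blocks —
(BN → Swish → Dropout → Conv1; BN → Swish → Dropout → ConvK;
BN → Swish → Dropout → Conv1) — with stage widths
(64, 160, 160, 400, 400, 1024, 1024) and block counts (2, 2, 2, 3, 3, 4, 4),
followed by global average pooling over time and one dense layer. ConvK is
an aggregated (grouped) convolution, kernel 16 in 16 groups. A
squeeze-excitation gate (temporal mean → dense → ReLU → dense → sigmoid,
reduction 16) scales channels before each residual addition. The first
block of each stage halves the temporal length; its shortcut max-pools the
identity by 2 and applies a kernel-1 projection when the width changes.
Counted depth = main-path convolutions + prediction dense =
(2+2+2+3+3+4+4) × 3 + 1 = 61; shortcut projections, SE layers, batch norms
and pooling are not counted, the only convention under which the arithmetic
gives 61.

Choices the stage table leaves open, fixed here:

- **Bottleneck inner width** equals the stage output width (no reduction):
  the plainest reading of "(Conv1, ConvK, Conv1)".
- **Downsampling** is stride 2 on the first block's ConvK with symmetric
  padding (7, 7), giving `floor(L/2)` for even and odd lengths alike and
  reproducing the published length column 2500, 1250, 625, 312, 156, 78,
  39. (An asymmetric 7/8 pad would give 313 at the 625→312 step.)
  Stride-1 ConvK uses (7, 8) so length is preserved.
- **First layer** projects 12 → 64 channels inside stage 1; there is no
  separate stem.
- **Dropout** defaults to 0.2; SE reduction to 16.
- A final BN → Swish precedes the pooling, standard for pre-activation
  residual networks.

Heads: ordinal (3 logits), four-class softmax (ablation), scalar
regression under squared error (ablation; its MAE is computed on the raw
continuous output — no rounding — so it has no class probabilities and no
AUC).

## Training protocol

Patient-wise splitting: fractions (default 0.8/0.1/0.1) apply to patients,
never records, so no subject leaks across splits. Optimization is Adam
(lr 0.001 full-scale default) with L2 weight decay 1e-4 — the package's
reading of "weight normalization to avoid overfitting" — and batch size 256
at full scale. The learning rate is multiplied by 0.3 when validation loss
stops improving (patience 3 epochs, floor 1e-5); after three reductions
without improvement training stops. Because the ordinal multi-task
objective is harder to optimize from scratch at full scale, the default
protocol is two-phase: phase 1 trains the backbone under a temporary
4-way softmax cross-entropy; phase 2 swaps in the 3-wide ordinal head
(re-initialized — the widths differ, so weights cannot carry over) and
fine-tunes under the cumulative BCE. One master seed drives split, batch
order and head initialization; runs are exactly reproducible.

## Numerical core

The network runs on a compact NumPy reverse-mode autodiff engine written
for this package (tape of ~200 nodes; primitives: grouped/strided/padded
1D convolution, max pooling, fused training-mode batch norm, fused swish,
sigmoid/softplus/log/exp, matmul, reductions, indexing). Default parameter
dtype is float32; float64 is available and used by the finite-difference
tests that verify every primitive's gradient. Losses are computed in
logit space (`softplus(z) − y·z`; log-sum-exp for the softmax) for
stability; the probability-space loss clips to [1e-7, 1 − 1e-7]. Checked
invariant: the logit-space loss agrees with the probability-space form to
1e-9 over random batches.

## Preprocessing and I/O

Raw signals are band-passed 0.5–50 Hz with a 3rd-order Butterworth filter
applied forward–backward (zero phase, so fiducial sample positions survive
for saliency overlays), independently per lead; the effective magnitude
response is the square of the single-pass response. WFDB I/O covers the
PTB-XL subset: format 16 (int16 little-endian), single `.dat` per record,
gain/baseline per signal, 12 leads; `physical = (raw − baseline) / gain`
in millivolts.

## Evaluation

MAE over predicted vs true integer levels; per-class one-vs-rest ROC-AUC
(midrank ties) with a macro average over classes present in the labels
(absent classes yield NaN and a warning); subgroups by sex and by age at
65 (≥ 65 upper group), each partitioning the test set, with records missing
a field excluded from that stratification only and counted. The
reviewer-agreement arithmetic reports, over the model's wrong predictions
re-read by an independent cardiologist, the percentage siding with the
model, with the original labels, and the residual disagreeing with both
(percentages rounded to two decimals).

## Synthetic data

The generator exists so every component is testable without the clinical
dataset. Beats are sums of five Gaussian bumps (P, Q, R, S, T) plus an ST
bump, projected to 12 leads by a fixed gain/polarity vector, with white
noise (0.03 mV) and sinusoidal baseline drift (0.1 mV at 0.25 Hz). Severity
grows monotonically with the class: ST offset 0 / 0.1 / 0.2 / 0.3 mV,
pathological Q depth 0.04–0.28 mV, RR jitter largest for the AF-like
medium-risk class (0.10 s), wide-QRS beat probability up to 0.35, and
class-specific heart-rate ranges. Records carry synthetic patient ids
(some patients own two records, so patient-wise splitting is non-trivial),
ages, sexes and PTB-XL-style `scp_codes` built from representative
statement codes of each class, so the full labeling pipeline runs on
fixtures unchanged.

What it does **not** emulate: realistic inter-lead morphology, pathology
beyond the injected gradients, electrode artifacts, or class overlap as
murky as clinical data. Passing the scaled-down experiments therefore
shows the machinery is correct and the ordinal structure is exploitable —
not that clinical-scale accuracy would be reproduced.

## Scaled-down experiments

Problem sizes are chosen so the whole suite runs in minutes on one CPU
core:

- **Ordinal recovery** (`experiments.ordinal_recovery_experiment`): a
  two-stage, 16/32-channel variant (kernel 8, groups 4, no dropout — nets
  this small trained this briefly do not overfit), 400 balanced records per
  seed, 5 seeds, 6 epochs, batch 16, lr 3e-3. Both heads train
  **single-phase** here: at this scale the ordinal head optimizes stably
  from scratch, and a shared protocol isolates the objective as the only
  difference between ordinal and softmax. Success: median test MAE well
  below the ~1.0 of a majority guesser, and the ordinal head's median MAE
  not worse than the softmax head's.
- **Saliency localization** (`experiments.anomaly_localization_experiment`):
  a seven-stage narrow variant keeps the full depth pattern; records with a
  1-s oscillation burst at a random position are separated from plain
  records, then deepest-stage Grad-CAM saliency is compared inside vs
  outside the burst window on held-out anomalous records.

## Grad-CAM for 1D signals

For a chosen layer and target score, channel weights are the temporal mean
of the score's gradient w.r.t. the layer activation; the map is the
rectified weighted channel sum, linearly interpolated to the input length
for overlay. The default target is the derived class probability (so the
map answers "what drives the probability of this critical value"); a single
cumulative logit can be targeted instead, and is the right choice on
records the model classifies confidently — a saturated probability has a
vanishing gradient and blanks the map, while the logit's does not. The
localization experiment targets the logit for this reason.
The temporal map is shared across
leads — the network mixes leads in its first convolution, so there is no
per-lead gradient path to separate — and the per-stage profile combines the
per-lead overlays (mean by default, sum optional) and min-max normalizes
each row to [0, 1] for cross-stage comparability; all-zero rows are kept at
zero rather than divided by a zero range.

## Known limitations

- The NumPy engine targets clarity and test-budget scale; full-scale
  training (tens of thousands of records, the 61-layer network) is out of
  its performance envelope.
- WFDB support is limited to the format-16 single-file layout used by the
  500 Hz PTB-XL records.
- The four-level scale has no sub-grading, and no action recommendation is
  attached to a value.
- The regression ablation's continuous output is compared against integer
  labels; rounding is available but off, matching its role as a baseline.
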