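# Methods

## Problem and model

The detector solves a per-segment binary classification: given single-lead
ECG at 200 Hz, decide every 256 samples (1.28 s) whether the current rhythm
is life-threatening (LTA = {VT, VF, VFL, PVT}) or anything else ("Other",
including sinus rhythm, atrial fibrillation and other supraventricular
rhythms). Training inputs are fixed 1792-sample sequences (7 segments,
8.96 s); at inference the network accepts any length that is a multiple of
256 and emits one decision per segment.

### Architecture

ECGnet is a pre-activation residual CNN. A stem convolution (kernel 16,
1 → 32 channels) is followed by `n` residual blocks, each containing two
(batch-norm → ReLU → convolution) stages with the second convolution
preceded by dropout (p = 0.2), an identity shortcut, and — at designated
blocks — 2× max-pool subsampling of the block input shared by both paths.
Channel doubling zero-pads the shortcut. A final batch-norm/ReLU feeds a
time-distributed fully connected head applied to every temporal slice with
shared weights. Eight 2× subsamplings in total map 1792 input samples to
exactly 7 output steps.

Reconstruction conventions (the source description leaves these open; all
are fixed in `ArchitectureSpec` and overridable):

* Kernel length 16 throughout, per the reference residual ECG architecture
  this family adapts. With kernel 16 the structural parameter counts of
  the three sizes are 10,465,698 (L), 7,677,538 (M) and 4,889,378 (S) —
  10.5/7.7/4.9 M at 0.1 M rounding, which is the acceptance check that the
  reconstruction is right.
* Subsampling placement: L (16 blocks, filters double every 4th) subsamples
  every alternate block; S (8 blocks, doubling every 2nd) must subsample
  every block; M (12 blocks, doubling every 3rd) subsamples the two latter
  blocks of each 3-block filter stage. Any placement of eight subsamplings
  preserves the parameter count; placement only shifts where compute is
  spent.
* Heads: v1 is a per-step 2-class softmax trained with cross-entropy
  (equivalent to binary cross-entropy with both classes explicit, and it
  keeps the time-distributed structure); v0 replaces softmax with per-class
  sigmoids and pools per-step logits with a global max over time, so the
  pooled probability equals the max of per-step probabilities exactly
  (sigmoid is monotone). v0 and v1 share every layer except the last two,
  which is what the transfer step relies on.

### Numerical engine

No deep-learning framework is used: layers are numpy float32 with analytic
backward passes, verified end to end against central finite differences.
Convolutions are evaluated as one strided batched matmul per kernel tap
(the fastest CPU strategy we measured; im2col materialization is
memory-bound). Subsampling by 2-sample max pooling keeps every convolution
at stride 1. The optimizer is Adam (lr 1e-3, β = 0.9/0.999), matching the
reference family's tuning; it is configuration, not a claim. Batch-norm
uses batch statistics in training and running statistics (momentum 0.1) in
inference.

## Preprocessing

Two chains, both after polyphase rational-ratio resampling to 200 Hz
(length = round(n·200/fs); upsampling is rejected since all source rates
are ≥ 200 Hz) and conversion to µV:

* **PT chain** (multi-label pre-training corpus): 4th-order Butterworth
  band-pass 0.5–40 Hz.
* **FT chain** (LTA-annotated recordings): mean subtraction → 5-sample
  centered boxcar (reflection padding) → 1 Hz high-pass → 30 Hz low-pass
  Butterworth — the classic AED monitor bandwidth.

Unstated orders are fixed as 1st-order high-pass and 4th-order low-pass,
recorded in `FilterSpec` and overridable. IIR stages default to zero-phase
(forward–backward) application for offline training; a causal mode exists
for streaming, with the expected phase differences. Standardization is
(x − μ)/σ with μ, σ pooled over training-split sequences only.

## Sequences, labels, splits, balancing

FT-style recordings are cut into consecutive non-overlapping 1792-sample
sequences (trailing remainder dropped). Each 256-sample segment takes the
label of the rhythm class covering the most of its samples after LTA/Other
mapping; an exact 128/128 tie goes to LTA (safety-first for a detector of
life-threatening events). Segments whose majority rhythm is Noise are
masked out of loss and metrics rather than deleted, preserving the fixed
input length; deletion of whole sequences is available by configuration.
PT-style 10 s recordings are truncated to their first 1792 samples; 5 s
records and records without a rhythm label are excluded with explicit
reasons.

Splits are subject-wise, 64/16/20 train/validation/test, by multi-label
iterative stratification over each subject's label set (greedy rarest-label
assignment with seeded tie-breaks); a label carried by a single subject
pins that subject to train.

Batch balancing replicates each LTA-pool sequence three times per epoch and
draws a fresh, equally sized subsample of the Other pool every epoch; a
sequence belongs to the LTA pool iff at least one of its valid segments is
LTA (labels live at segment level, so this sequence-level pooling is the
minimal consistent reading; majority-of-segments pooling is a flag).
Alternatives: inverse-frequency class weights in the loss, or no balancing.

## Transfer protocol

Pre-training minimizes multi-label BCE on pooled v0 probabilities with
early stopping on validation loss. Transfer copies every backbone tensor
(weights and batch-norm running statistics) bit-exactly into a fresh v1
model; the head keeps its new initialization. Fine-tuning freezes the
first `k` residual blocks: frozen parameters receive no updates *and*
frozen batch-norm layers use stored statistics even in training mode, so
frozen blocks are bit-identical before and after — the central correctness
property, asserted at bit level in the tests. `k` is selected by repeating
the fine-tune over a grid of depths and maximizing mean validation
macro-F1 (ties → smaller `k`); early stopping always monitors validation
loss, never MF1. Repeats differ only in weight-initialization and
data-order seeds; splits stay fixed.

## Confidence and alerts

Sliding the 1792-sample window in 256-sample steps gives every interior
segment 7 predictions; the majority label's vote fraction is its
confidence, quantized to {4/7, 5/7, 6/7, 1} for full traces. Edge segments
(< 7 covering windows) use the actual window count as denominator, and
even-split ties resolve to LTA, flagged on the prediction — the source
procedure does not specify edge handling, so this is a documented package
choice. A confident LTA (confidence ≥ τ, default 6/7) raises an alert; a
low-confidence LTA opens a pre-alert that escalates if any of the next
`h` segments (default 4, ≈ 5 s) is a confident LTA and clears otherwise.
τ and `h` are configuration: the mechanism is proposed without constants.
In streaming use, a segment's vote is final only after its last covering
window, i.e. with ≤ 7.68 s latency.

## Evaluation and statistics

Metrics on the 0–100 scale: Se, Sp (LTA positive), BAC = (Se + Sp)/2,
BER = 100 − BAC, accuracy, Cohen's κ (standard observed-vs-chance
formula), weighted and macro F1. Metrics undefined on a degenerate input
are NaN, never zero. AHA compliance is Se ≥ 90 and Sp ≥ 95. Phase
partitioning marks the three segments before and the three from each
ground-truth change point as transitory (the change segment is the first
of the new rhythm; the exclusive reading `{c−3..c−1} ∪ {c+1..c+3}` is a
flag — printed summary tables cannot disambiguate the two). Windows never
cross recording boundaries and overlaps merge.

Model comparison: one-sided Mann–Whitney U on per-run metric samples
("greater" for quality metrics, "less" for BER), with exact enumeration
over all group assignments for n₁+n₂ ≤ 20 (midranks; ties handled by the
enumeration itself) and the tie-corrected normal approximation beyond;
effect size r = 1 − 2U/(n₁n₂). One property often asserted of wF1 is
false and deliberately not claimed here: swapping the class labels on both
truth and prediction exchanges per-class F1 values together with their
supports, so wF1 — like MF1 — is invariant under the swap; the two differ
from each other exactly when supports are unequal.

## Synthetic data: what it emulates, what it does not

The generator produces two cohort styles with the statistical structure
the pipeline assumes: FT-style minutes-scale recordings at 250/360 Hz with
annotated instantaneous transitions into VT/VF/VFL/PVT-like rhythms
(≈ 12 % LTA time by default, mirroring ambulatory-database imbalance, with
occasional Noise spans) and PT-style 10 s, 500 Hz recordings carrying 1–2
labels from a 10-name non-LTA vocabulary. Waveforms are parametric
analytic shapes — Gaussian-bump QRS trains (60–100 bpm sinus, irregular-RR
fibrillation-like, 105–150 bpm tachycardia) and amplitude/frequency-
modulated oscillations (VT/VFL at 150–250 bpm; VF/PVT with 4–7 Hz dominant
frequency and cycle-to-cycle jitter) — plus white noise (20 µV), sinusoidal
baseline wander (50 µV) and µV-scale amplitudes (sinus R ≈ 1000 µV) to
exercise unit conversion. Default recording length is ~50–60 s: long
enough for several sequences and both rhythm phases per subject while
keeping the full desk-scale protocol in the minutes range on one CPU.

Randomness is PCG64 with per-subject substreams derived as
`SeedSequence((cohort_seed, subject_index))`, so cohorts are bit-identical
across runs and platforms and a subject's waveform does not depend on
cohort size.

By design the VF/sinus contrast is linearly separable by 4–7 Hz relative
bandpower (asserted in the tests). Consequently, passing desk-scale
training tests demonstrates that the *pipeline* — labeling, balancing,
transfer, freezing, voting, evaluation — is correct, not that the model
reaches any particular performance on real ECG: real morphology,
electrode artifacts, inter-patient variability and ambiguous transition
rhythms are absent. Noise levels are configurable defaults, not calibrated
to any source dataset.

## Desk-scale protocol and sizes

The end-to-end exercise in the test suite uses 200 PT-style + 30 FT-style
recordings, the S backbone, pre-training capped at 8 epochs and fine-tunes
at 5 (patience 2), batch 64, a freezing grid {0, 2, 4} with 2 repeats, and
5 seeds per training arm — sized to finish in minutes on one CPU while
still exercising every stage. Full-scale defaults in `TrainConfig` remain
500 epochs, patience 30, batch 512 (pre-training; the fine-tuning batch
size is not pinned by the source and defaults lower). On the synthetic
task both training arms saturate, so the scratch-vs-transfer comparison is
asserted as non-inferiority (one-sided Mann–Whitney, α = 0.05) rather than
strict superiority: with an easily separable task there is no data-scarcity
gap for transfer to close, and the exercise verifies the protocol's
mechanics, not the real-data effect size.

## Known limitations

* Schematic ECG morphology; no 12-lead synthesis; no wearable-specific
  artifacts.
* The WFDB dialect covers single-segment format-16 records and rhythm
  (aux-string) annotations only.
* The receptive field of the backbone (~30 segments) exceeds typical
  inputs, so per-step outputs are not strictly local to their segment;
  the temporal contract tested is one output per 256 samples and
  per-segment sensitivity.
* Confidence is a vote fraction, not a calibrated probability.
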