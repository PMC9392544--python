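# Methods

This note records the scientific and numerical choices behind `eegresp`:
what the pipeline computes, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Pipeline overview

The unit of classification is a 1 s epoch (500 samples × 19 channels) of
resting-state EEG on the 10–20 montage, referenced to linked earlobes
(A1+A2). A recording contributes `floor(n_samples / 500)` epochs, all
inheriting the recording-level label (session pre/post, or responder/
nonresponder from the ≥ 50 % BDI-II reduction rule). Eyes-open and
eyes-closed recordings are pooled under the same label.

### Preprocessing

Per recording, in order:

1. **ICA artifact removal.** FastICA (negentropy maximisation, unit-variance
   whitening) with as many components as channels, so that with an empty
   rejection set the decomposition reconstructs the input to numerical
   precision. Components are rejected when their absolute correlation with
   the frontal blink proxy (mean of Fp1 and Fp2) is ≥ 0.8 or their excess
   kurtosis is ≥ 5 (both configurable). ICA runs on the raw signal — the
   artifact structure it must isolate is strongest there — and filtering
   follows.
2. **50 Hz notch** (IIR, quality factor 30) for power-line interference.
3. **0.1–60 Hz band-pass**, elliptic order 4 with 1 dB pass-band ripple and
   40 dB stop-band attenuation. A Chebyshev type-II design (order 4, 40 dB)
   is selectable; for that design the band edges are stop-band edges, which
   is inherent to the Chebyshev-II form.

All filters are applied forward-backward (`sosfiltfilt`), so the effective
magnitude response is squared (a 1 dB-ripple pass band becomes up to 2 dB)
and the phase response is exactly zero — waveform latencies are preserved,
which the test suite checks by cross-correlation. Filters are validated as
stable (all poles inside the unit circle) at design time.

### Augmentation

The training partition of each fold grows by `fraction_per_fold × n_folds`
(default 2 % × 10 = 20 %), with totals rounded **up** to a whole epoch.
Each artificial epoch is the element-wise mean of `n_average = 2` randomly
drawn same-class training epochs, after which 2 % of time instances per
channel are replaced by the corresponding raw values of one parent, keeping
the artificial epoch from being over-smoothed. Same-class averaging is a
requirement, not an option: cross-class averages would have no defensible
label. Artificial epochs carry provenance (parent row indices) and are
never placed in validation or test partitions; per-class allocation uses
largest-remainder rounding so class proportions change by less than one
epoch.

For a 27,683-epoch dataset this yields 33,220 after augmentation and a
29,898 / 3,322 train-validation / test split per fold; a 28,050-epoch
dataset yields 33,660. One historical column of the sizing arithmetic
(12,465 → 16,620) is not consistent with any uniform per-fold fraction
(the rule gives 14,958); the growth fraction is therefore exposed as
configuration rather than special-cased.

### The network

Valid stride-1 1D convolutions and non-overlapping max-pooling compress
each epoch before a three-layer LSTM stack and a 2-unit sigmoid read-out.
Kernel and pool lengths are not free choices: given the published output
lengths and parameter counts of the layer stack (497×128, 124×128, 121×64,
30×64, 27×32, 6×32, 3×16, 2×8, 1×8, 1×50, 1×25, 25, 2 and 9,856 / 32,832 /
8,224 / 2,064 / 264 / 11,800 / 7,600 / 5,100 / 52 parameters), the unique
consistent sizes are s = 4, 4, 4, 4, 2 and d = 4, 4, 4, 2, which
`default_architecture()` hard-codes. LSTM parameter counts follow the
single-bias convention, 4(u(m+u)+u), which reproduces the printed values
exactly. After the last pooling stage the sequence axis has length 1, so a
flattening step before the LSTM is a no-op and the 1×8 feature sequence is
passed directly.

Implementation choices:

* **Loss/output.** Two sigmoid output units trained with per-unit binary
  cross-entropy against one-hot targets; predicted probabilities are the
  renormalised sigmoids. (A softmax pair would be conventional; the
  two-sigmoid form is retained and behaves equivalently for binary
  decisions.)
* **Optimiser.** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch size 128,
  learning rate 1e-3, early stopping on validation loss with patience 5
  (all configurable); best-epoch weights are restored.
* **Standardisation.** Inputs are standardised per channel using training-
  partition statistics. Raw microvolt inputs stall training; the scaling is
  a deliberate addition and is recorded on the fitted model.
* **Initialisation.** Glorot-uniform weights, zero biases except the LSTM
  forget gate (1.0). Computation in float32 by default (float64 available;
  the numerical gradient check runs in float64). LSTM pre-activations are
  clamped at ±60 before the gate nonlinearities to keep `exp` finite in
  float32; the clamp is far outside the operating range of trained nets.
* **Backprop correctness** is guarded by a central-difference gradient
  check over every parameter family and by brute-force oracles for the
  convolution and pooling primitives.

### Evaluation protocol

Stratified k-fold cross-validation (default k = 10). Per fold: one fold is
the test partition and the remaining segments are split 7:2 into training
and validation, giving the global 70/20/10 split; only the training
partition is augmented. Metrics are computed per fold and summarised as
mean ± SD over folds; confusion counts are summed. κ uses the standard
marginal-product chance correction; AUC is the rank-sum (Mann-Whitney)
statistic with ties counted one half, computed from the positive-class
probability.

Two split policies:

* `segment_level` (default for fidelity with segment-count bookkeeping):
  epochs are stratified individually. Epochs of one subject — and of one
  recording — then straddle train and test, so scores are optimistic about
  subject-level generalisation.
* `subject_level` (recommended): all epochs of a subject share one fold;
  train/validation splitting is also by subject and stratified by the
  subject's label set, so validation always contains every class. The
  report records which policy produced it.

A degenerate fold (single-class test partition) is an error; a fold where
the classifier predicts one class only yields NaN for the undefined rates
(with a warning) rather than a silent zero.

## The synthetic cohort

The generator emulates the acquisition geometry the pipeline assumes —
19 channels, 500 Hz, ten-minute eyes-open/eyes-closed recordings, pre/post
sessions, cohort of 25 + 25 with 11 female / 18 male responders by default —
and a phenomenological signal model:

* **Background**: per-channel 1/f (pink) noise, 10 µV RMS, spatially mixed
  by one fixed matrix shared by all subjects. Sharing the matrix is
  deliberate: ICA has spatial structure to find, but subject identity is
  not encoded in the background, so a zero-effect cohort is exchangeable
  and null calibration of the classifier is meaningful.
* **Alpha rhythm**: amplitude-modulated 10 Hz carrier with slow phase
  drift, posterior-dominant topography, 1.6× stronger eyes-closed.
  A subject's class effect scales alpha amplitude by (1 + effect) and
  tilts the F3/F4 asymmetry; the session effect applies the same scaling
  post-treatment. Effects are band-power stand-ins chosen for testability —
  they are not claims about the real electrophysiology of rTMS response,
  which the source data do not disclose.
* **Artifacts**: Poisson blink transients (300 ms Gaussian bump, frontal
  weights, 80–140 µV), temporal-channel muscle bursts (0.5 s, ~15 µV,
  high-pass-shaped noise), 50 Hz line interference (default 4 µV), and
  sub-0.1 Hz electrode drift (default 20 µV).
* **BDI-II scores**: drawn per sex × response group from normal
  distributions truncated to non-negative integers (group means/SDs default
  to the observed cohort statistics), then minimally adjusted so the
  intended label satisfies the 50 %-reduction rule exactly.

What passing tests therefore show: the implementation's arithmetic,
filters, decomposition, protocol and optimiser behave correctly, the
pipeline does not manufacture signal where none exists, and it recovers a
genuine spectral class difference end to end. What they do not show:
performance on real patients, where class differences are subtler,
non-stationary, and confounded with medication, vigilance and artifact
load.

EDF export writes 16-bit files with per-channel symmetric physical ranges
(quantisation error ≤ one digital step, verified against an independent
reader); recordings are truncated to whole 1 s data records.

## Problem sizes used in automated checks

The end-to-end checks run the full pipeline at reduced scale, chosen as
realistic-but-small study conditions: cohorts of 10 subjects per class,
60 s single-condition recordings (1,200 epochs), two subject-level folds,
and short Adam schedules (5 epochs for the null check across three seeds,
14 for the recovery check). Null calibration asserts pooled test accuracy
0.5 ± 0.05 and κ within ± 0.1; recovery asserts accuracy ≥ 0.9 with a
strong injected effect (class_effect = 2.5). The architecture itself is
never scaled down.

## Known limitations

* The CNN-LSTM trains on CPU in NumPy; at full study scale (≈ 28,000
  epochs × 10 folds) training is possible but slow — the implementation
  targets correctness and reproducibility, not throughput.
* ICA rejection uses two simple criteria (blink-proxy correlation,
  kurtosis); no attempt is made at full artifact taxonomies.
* The generator's artifacts are stereotyped; real ocular/myogenic activity
  is far more variable, so ICA performance on real data will differ.
* `segment_level` splitting is provided for bookkeeping fidelity but leaks
  subject identity; subject-level scores are the ones that support
  generalisation claims.
* No statistical comparison between the five dataset definitions is
  provided; the per-fold SDs describe variability, not significance.
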