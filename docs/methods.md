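# Methods

## Problem setting

The package classifies anuran species from single-label call recordings:
mono audio, nominally 44100 Hz and ~20 s per clip, 35 species.  The design
is a *coefficient sweep*: instead of one feature vector per clip, each clip
contributes 40 vectors obtained at 40 settings of a filter coefficient (the
LPC prediction order, or the MFCC pre-emphasis coefficient).  With one clip
per species this yields the canonical 1400 × 10240 feature matrix on which
all classifiers are benchmarked.

## Audio standardization

Clips are channel-averaged to mono, band-limited-resampled to the target
rate (polyphase, rational ratio), truncated or zero-padded to exactly
`round(rate × duration)` samples, and peak-normalized to max |x| = 1.
Peak normalization is a deliberate choice: the LPC gain and the MFCC
log-energies otherwise depend on the recording level, which carries no
species information.  All-zero clips pass through with a warning rather
than an error so corpus assembly is robust to silent files.

## LPC features

An order-P all-pole model is fitted to the *whole* Hamming-windowed clip:
autocorrelation to lag P (computed by FFT; identical to the direct sum),
then the Levinson–Durbin recursion for the Toeplitz normal equations.
Conventions:

* `predictor_coeffs` a₁…a_P satisfy L̂[k] = Σ a_m L[k−m];
  `denominator_coeffs` A_j = −a_j make the transfer-function denominator
  1 + Σ A_j z^{-j} literal.  Both are exposed to avoid sign ambiguity.
* gain G = √(error_power), the unit-variance-excitation convention.
* The model is all-pole: the production model's moving-average term is
  dropped (q = 0, B₀ = 1), which is the standard LPC reduction when only
  prediction coefficients are extracted.

The feature vector is the envelope in dB at F frequencies ω_i = π·i/F,
i = 0…F−1, evaluated with one zero-padded FFT; a 1e−12 magnitude floor
keeps the log finite.  **Interpretation note:** mapping one ~882000-sample
clip to exactly 10240 values is done by sampling a single whole-clip
envelope at 10240 frequencies.  Frame-wise LPC with concatenation is an
alternative reading of the same output geometry; the whole-clip reading is
the package's documented choice, producing exactly one envelope per
(clip, P) pair.

Levinson–Durbin raises on r₀ ≤ 0 (degenerate signal) and on any reflection
coefficient reaching magnitude 1 (numerically singular input), naming the
recursion stage.

## MFCC features

Chain per frame: pre-emphasis y[n] = x[n] − α·x[n−1] (y[0] = x[0]) →
2048-sample frames with 1024 hop → Hamming window → magnitude-squared FFT →
26 triangular mel filters between 0 Hz and Nyquist (mel(f) = 2595·log10(1 +
f/700)) → natural log with a 1e−12 floor → orthonormal DCT-II, keeping 13
cepstra.  Frame length, hop, filter and cepstra counts are canonical
speech-processing defaults; the source study fixes only the output length
(10240) and the α sweep (0.22…1.00 step 0.02).  The frame-by-cepstra matrix
(860 × 13 for a standard clip) is flattened time-major and truncated to
10240 (zero-padded if shorter), keeping the earliest frames.

## Synthetic corpus

The generator emulates what the feature extractors measure — class-specific
spectral envelopes — not any real species' acoustics.  Each species spec
is: fundamental frequency (35 values geometrically spread over 400–6000 Hz,
seeded jitter, adjacent ratios ≥ 1.05), 3–8 harmonics with per-harmonic
decay 0.5–0.9, a rectangular pulse gate at 2–15 Hz with duty 0.3–0.8, slow
sinusoidal FM (depth ≤ 30 Hz at 3 Hz), and white Gaussian noise at an SNR
of 15–25 dB.  Everything is deterministic in (seed, parameters).

What it does *not* model: background chorus, reverberation, overlapping
callers, recording-chain coloration, within-species call variability.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that it separates classes that differ in spectral envelope;
they do not predict accuracy on real field recordings.

One clip per species is the default, mirroring the study design in which
all 40 coefficient rows of a species derive from one recording.  This makes
the random row split leak near-duplicate rows across partitions — the
generator supports `clips_per_species > 1` and the dataset module a
`group_aware` split mode for leakage-free evaluation, but the default
`row_random` mode replicates the study protocol.

## Dataset and splitting

Rows are ordered species-major, coefficient-ascending; labels are the
strings `X_YY` (species X, coefficient printed as integer for LPC and with
two decimals for MFCC).  The "multi-label" phrasing of the source material
is implemented as single-label multi-class with coefficient metadata: every
row has exactly one species target, matching the classifiers' 35-way
output.  The 70/30 split is stratified per species (round(0.3·40) = 12 test
rows per species → 980/420), guaranteeing every class appears on both
sides; the split is deterministic in its seed.

## PCA

Scatter-matrix PCA with K = 200 components, computed by thin SVD of the
centered training matrix (N ≪ F, so the explicit 10240² scatter is never
formed; eigenvalues are the squared singular values and the equivalence
with the explicit eigendecomposition is asserted in tests).  Components are
sign-fixed (largest-magnitude entry positive) for reproducibility.  PCA is
fitted on the training partition only and applied to both partitions; a
`fit_on_all` switch exists to replicate the permissive fit-before-split
reading, but leaks test information and is off by default.

## Classifiers

**DNN.** Fully connected stacks with logistic-sigmoid hidden units and an
affine 35-way output; hidden widths fixed per named depth (12/16/20/24
layers).  Initialization is the package's own scheme, chosen because
sigmoid stacks this deep do not train from small random weights: hidden
weights are random orthogonal matrices scaled by 6 (the logistic slope at
0 is 1/4, so gain 4 makes the layer Jacobian isometric; the extra factor
1.5 keeps 20–24-layer stacks just above the attenuation threshold), and
hidden biases are set to −0.5·Σ_in w so each unit's pre-activation is
centered given sigmoid inputs with mean ≈ 0.5.  The output layer is plain
Glorot.  Without the centering and orthogonal gain, the 20- and 24-layer
stacks sit at exactly uniform output (loss ln 35) for hundreds of epochs.

**LSTM.** Two stacked layers of H ∈ {200, 300, 500, 700} units applying
the standard gate equations (input/forget/cell-candidate/output, elementwise
products, zero initial state), with the class read from the top layer's
final hidden state through an affine map.  A length-L feature vector enters
as a T × D sequence with L = T·D: T = 40 for raw 10240-length features
(D = 256) and T = 8 for 200-dimensional PCA scores (D = 25).  The sequence
layout is a declared convention — the source material feeds 10240-length
vectors to an LSTM without stating one.  Gate weights are Glorot-uniform,
seeded; forget biases start at 0.

Backpropagation (including full-length BPTT) is hand-written in NumPy and
verified against central finite differences at 1e−8 tolerance.

## Optimization

Adam from its defining recurrences: X ← ρX + (1−ρ)g², F ← ρ_f F + (1−ρ_f)g,
bias-corrected by (1−ρ^t) and (1−ρ_f^t), update w ← w − lr·F̂/(√X̂ + ε),
with ρ = 0.999, ρ_f = 0.9, ε = 1e−8 (the optimizer's canonical constants;
the source states the recurrences but not the decays).  The loss is softmax
cross-entropy — the standard multi-class choice; the source never names its
loss.  `TrainConfig` defaults mirror the study protocol (1000 epochs,
lr 2e−5, batch 1400 = full batch).  Training is deterministic under the
config seed in single-threaded execution.

## Problem sizes used in tests and the acceptance run

The structural checks run at the full study geometry (35 species, 20 s at
44.1 kHz, 1400 × 10240 matrices, K = 200).  Classifier training in the
end-to-end checks uses the package's CPU-sized setting — mini-batches of
128 at learning rate 1e−3, 300 epochs for the DNN and 15 for the LSTM —
rather than the protocol's 1000 full-batch epochs at 2e−5, which targets
GPU hardware; both stay well inside the ≤ 1000-epoch envelope, and with
them the two flagship configurations (LPC-PCA-DNN-12, MFCC-LSTM-2×200)
reach perfect held-out accuracy on the synthetic corpus.  The 16-model
trainability sweep uses 320-point envelopes and PCA-200 inputs.  Unit
tests run a miniature geometry (5 species, 2 s at 8 kHz, 256-point
features).

## Numerical choices

* Magnitude/log floors: 1e−12 throughout (envelope, filterbank energies).
* Autocorrelation by FFT (zero-padded to ≥ 2N, exact linear correlation).
* Gradient checks at 1e−8; Levinson–Durbin vs dense Toeplitz solve at
  1e−8; PCA vs SVD at 1e−6 relative; Adam vs hand-unrolled at 1e−12.
* Feature scaling before classifiers: per-feature z-scoring with training
  statistics.  After PCA the scores are divided by one *global* standard
  deviation — per-component scaling would equalize the eigen-spectrum and
  amplify low-variance noise directions, which measurably destroys
  cross-coefficient generalization.
* Ties and degenerate inputs: all-zero clips raise in LPC (r₀ = 0) and hit
  the log floor in MFCC; eigenvector signs fixed deterministically;
  argmax prediction ties resolve to the lowest class index (NumPy
  convention).

## Known limitations

* The whole-clip LPC envelope and the flatten-truncate MFCC mapping are
  documented interpretations of an output geometry the source leaves
  unspecified.
* Difference ratios are computed as 100·(treated − baseline)/baseline and
  rounded to one decimal; published rows whose printed ratios disagree
  with their printed accuracy pairs by more than rounding are attributable
  to unrounded internal values and are not reproduced.
* Timing columns (training period) are recorded for information only;
  they are hardware-dependent and never asserted.
* The synthetic corpus makes the classification task easier than real
  field audio; headline accuracies here characterize the pipeline, not
  expected field performance.
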