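# Methods

## Problem and model

The package classifies per-window emotional state (low/high arousal,
valence or dominance) from multichannel EEG. Three feature families are
combined:

1. **Functional connectivity (spatial).** For each window the
   phase-locking value between every channel pair,
   `PLV = |n⁻¹ Σₜ exp(i(φₓ(t) − φᵧ(t)))| ∈ [0, 1]`,
   where φ is the instantaneous phase of the analytic signal. The full
   symmetric NC×NC matrix (unit diagonal, NC(NC+1)/2 unique entries)
   expresses how strongly channel pairs phase-synchronize.
2. **Band power (frequency).** Per channel, the mean squared FFT
   magnitude over the bins of the five canonical EEG bands
   (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz),
   an NC×5 matrix.
3. **Temporal evolution.** Each 1 s sample is swept with 0.5 s
   sub-windows stepping by 16 samples (5 steps), each yielding a fused
   NC×(NC+5) matrix `[PLV | bands]`; the sequence of these matrices is
   the classifier input.

The classifier applies two conv/ReLU/max-pool/dropout blocks
time-distributed over the step axis (frequency–spatial stage), two GRU
layers with dropout (temporal stage; the second returns its final
state), an attention re-weighting `out = softmax(Wv) ⊙ v` over the flat
feature vector, then a ReLU dense layer, dropout and a 2-unit softmax.
Training is Adam on cross-entropy (defaults: learning rate 0.001, 100
epochs, batch 200).

The network is implemented directly in NumPy with hand-written
forward/backward passes for every layer. This keeps each equation of
the model inspectable and unit-testable against closed-form oracles,
and an end-to-end central-difference gradient check verifies the
composed backpropagation to 1e−4.

## Design choices where the design was open

- **Phase estimator.** PLV needs an instantaneous phase; we use the
  analytic-signal (Hilbert) phase of the broadband window, the standard
  choice in the connectivity literature. Per-band PLV can be obtained
  by band-filtering before windowing, but is not the default.
- **Gamma upper edge 45 Hz.** "Gamma" is open-ended above 30 Hz; 45 Hz
  keeps the band clear of the 64 Hz Nyquist limit at 128 Hz sampling
  and of 50/60 Hz mains interference.
- **Fusion layout.** The full symmetric PLV matrix (not the packed
  triangle) is concatenated with the band matrix along columns. Each
  row then corresponds to one channel, so 2-D convolutions see
  spatially coherent structure; packing the triangle would destroy the
  row alignment.
- **Band-column standardization.** PLV is bounded in [0, 1] while raw
  band powers are unbounded and scale with amplitude squared; the band
  columns are z-scored per cross-validation fold using statistics of
  the training split only (test-set leakage would otherwise corrupt
  the LOSO chance-level guard).
- **Attention softmax axis.** W is a square d×d matrix and the softmax
  runs over the d feature components — the only axis for which the
  output of `softmax(Wv) ⊙ v` keeps the input dimension for a flat
  vector. A vector-valued W variant would give a scalar gate instead
  and is intentionally not the default.
- **Update-gate convention.** The state update is
  `hₜ = (1−zₜ)⊙hₜ₋₁ + zₜ⊙h̃ₜ`: a saturated update gate (z→1) adopts
  the candidate state, z→0 carries the previous state through. The
  reset gate multiplies the *projected* previous state,
  `r ⊙ (U_h h_{t-1})`.
- **Layer sizes.** Layer counts are fixed by the architecture (two conv
  blocks, two GRU layers, one dense layer); sizes are not. Defaults are
  conventional: 3×3 kernels with 32/64 filters, 2×2 pools, conv dropout
  0.25, GRU units 64/32 with dropout 0.3, dense 128, head dropout 0.5.
  `HyperParams.small()` (8/16 filters, 32/16 GRU units, dense 32) is the
  desk-scale preset used throughout the tests, where inputs have 8
  channels rather than 32.
- **Fold construction.** Subject-dependent folds are stratified by
  class and split at the sample level. Note that heavily overlapping
  windows (the 2 s / 0.125 s ablation segmentation) share signal
  content across samples, so sample-level folds are optimistic there;
  trial-level splitting is the hygienic alternative when absolute
  numbers matter.
- **Seed fan-out.** A single run seed is split into per-subject,
  per-fold and per-initialization streams with
  `numpy.random.SeedSequence((seed, subject, fold))`, so any single
  fold can be reproduced in isolation.

## Synthetic data: what it emulates and what it does not

`SyntheticSpec` plants the class structure exactly in the two measured
feature families:

- Each channel carries a unit-amplitude carrier drawn uniformly from
  the carrier band (default alpha, 8–13 Hz) with a slowly drifting
  phase (random-walk sd 0.1 rad/sample). Designated channel pairs share
  their carrier frequency and, in high-class trials, mix a common phase
  with an independent phase at weight (1−κ). The independent phase
  combines an in-band frequency detuning (the channel's effective
  frequency is redrawn uniformly within the carrier band) with the slow
  walk: uncoupled phase differences then sweep linearly and windowed
  PLV decoheres toward chance without the heavy Lorentzian tails a
  fast random walk would leak into neighbouring bands. Measured on
  0.5 s windows, mean coupled-pair PLV rises monotonically from ≈0.5
  (κ=0) to exactly 1 (κ=1, noise-free).
- Each channel additionally carries one sinusoid per canonical band
  (2/6/10/22/38 Hz — even frequencies lie on exact FFT bins for 0.5 s
  and 1 s windows at 128 Hz) at amplitude 0.5; high-class trials
  multiply selected band amplitudes by √gain so the class band-power
  ratio equals the requested gain (measured ratio ≈1.8 for gain 2,
  within the ±20 % Monte-Carlo band — residual dilution comes from
  carrier spectral leakage, which is class-independent). Members of a
  coupled pair share band-component phases so that κ=1 with zero noise
  makes the pair identical (PLV exactly 1).
- White Gaussian noise (default sd 0.1 against carrier amplitude 1) is
  added per channel; trial scores are set to the dataset threshold
  (high) or threshold−1 (low), deliberately exercising the
  "score < threshold → low, otherwise high" boundary rule.
- One RNG stream per subject is derived from (seed, subject index), so
  a subject's data is bit-reproducible regardless of how many subjects
  are generated.

This emulates *feature-level* class structure only. It does not model
volume conduction, electrode montage geometry, 1/f background spectra,
artifacts (EOG/EMG), inter-subject variability or non-stationarity
beyond phase drift. Passing tests therefore demonstrate that the
pipeline recovers planted phase-coupling and band-power differences —
not that it attains any particular accuracy on real recordings.

## Problem sizes used in tests

End-to-end runs use 5 subjects × 25 trials of 8 s (200 one-second
samples per subject, 8 channels, 2 coupled pairs), the small layer
preset, 5-fold subject-dependent CV and LOSO, and 20 training epochs at
batch 32 (at n≈160 per fold, batch 32 gives the optimizer enough steps
within 20 epochs). Under full coupling and a 2× beta gain the
subject-dependent grand mean accuracy is ≈0.99; with no planted signal
LOSO accuracy stays within 3 binomial sd of chance, which guards
against fold leakage.

## Numerical notes and degenerate inputs

- Convolutions are stride-1 and same-padded; pooling is non-overlapping
  with trailing rows/columns dropped (they receive zero gradient).
- All-zero channels have undefined phase: they are flagged and given
  zero phase rather than NaN.
- F1 with no positive labels or predictions (2TP+FP+FN = 0) is reported
  as 0 with a degenerate flag.
- A band too narrow to contain an FFT bin at the current window length
  yields 0 power with a resolution warning; bands beyond Nyquist are
  errors.
- Windows never cross trial boundaries and partial tail windows are
  discarded (half-open [start, start+len), 0-based) — a 60 s trial
  yields exactly 60 windows at 1 s / 1 s and 465 at 2 s / 0.125 s.
- Resampling is polyphase with anti-aliasing; equal-rate resampling is
  a bitwise pass-through.
- The DEAP loader drops the 3 s pre-stimulus baseline by default so a
  subject segments into 40 × 60 = 2400 one-second samples
  (`drop_baseline=False` keeps all 63 s). DREAMER film clips have
  unequal lengths; the trailing 60 s of each clip are kept by default.

## Known limitations

- The NumPy network is single-threaded per BLAS call and has no GPU
  path; it is sized for method validation, not for full-corpus
  training runs.
- Default layer sizes are conventional choices, not a published
  reference configuration; absolute accuracies on real corpora will
  depend on them.
- Sample-level folds with overlapping windows are optimistic (see
  above); use trial-level splits for publication-grade numbers on
  densely overlapping segmentations.
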