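# Methods

This note documents the models, parameters and numerical choices behind
`ltyseiz`, and what the packaged synthetic benchmark does and does not
demonstrate.

## Synthetic EEG generator

The generator (`synthdata`) emulates long-term 18-channel scalp EEG at
256 Hz in microvolts:

* **Background**: white noise shaped in the frequency domain to a 1/f
  power spectrum (amplitude ∝ f^−1/2), default variance 800 µV²; one
  alpha (8–12 Hz) and one beta (13–30 Hz) sinusoid per channel with
  random frequency and phase (alpha variance 100 µV²); powerline
  sinusoids at 60 and 120 Hz (8 and 3 µV amplitude) with a common phase
  across channels.  Total background RMS is ≈ 30 µV, physiologically
  plausible and comfortable for EDF 16-bit scaling.
* **Ictal episodes**: a sinusoid at the 3 Hz fundamental plus its first
  two harmonics with amplitudes 1 : 0.5 : 0.25, scaled to
  `ictal_amplitude_gain` × background RMS, cosine-tapered over one second
  at each edge, added with a shared phase to a random subset of at least
  half the channels (creating inter-channel ictal correlation).  Episode
  intervals are half-open `[start, end)` in seconds, pairwise disjoint
  with 5-s margins; placement distributes the free slack over the gaps
  with a Dirichlet draw, so any feasible layout succeeds and an
  infeasible one raises immediately.
* **Determinism**: all randomness flows from one `numpy` Generator seeded
  by the config; identical configs give bit-identical signals and (via
  the deterministic EDF encoder) bit-identical files.

This is a *detectability* model, not clinical electrography: there are no
artifacts (EMG, blinks, electrode pops), no evolving seizure morphology,
no inter-subject variability.  Tests passing on it show the pipeline's
plumbing, filtering, feature extraction, training and evaluation are
correct and leak-free — not that the classifier would reach comparable
numbers on hospital recordings.

## Preprocessing

* Filters are 4th-order Butterworth sections applied forward-backward
  (zero phase).  First-order transfer-function sketches of the
  band-stop/high-pass stages are not realizable discrete filters as
  written, so the stated cutoffs and stop bands are honored as *response
  contracts*, verified spectrally in the tests: ≥ 40 dB attenuation at 60
  and 120 Hz, passband gain within ±1 dB at 10 and 100 Hz, DC rejection,
  ≥ 6 dB at 0.2 Hz.
* Resampling is polyphase (`scipy.signal.resample_poly`), exact for the
  512→256 and 1024→256 ratios of typical source data; upsampling is
  refused.
* Windows are 64 s (16,384 samples), starts at multiples of the stride,
  0-based, half-open in time.  Labels: ictal if ≥ 50% of the window
  overlaps a seizure interval, interictal if the overlap is zero;
  ambiguous windows are dropped by default (configurable) because mixed
  windows corrupt both classes.
* Class balance: additional ictal windows are re-cut from annotated
  seizure spans at a 16-s stride (75% overlap) until the class ratio
  reaches the target; background windows are never duplicated, existing
  windows and labels are never altered, and every added window records
  its source offset (provenance is asserted sample-exactly in tests).

## Features

* **STFT**: Hann window of 256 samples (1 s), hop 128 (50% overlap),
  frames fully inside the window: (16384 − 256)/128 + 1 = 127 frames at
  1 Hz bin resolution.  Retained bins 1–114 Hz: above the 1 Hz high-pass
  cutoff and below the 117 Hz stop-band edge — the unique natural
  configuration reproducing the 127 × 114 reference geometry.  Magnitudes
  are compressed as log(1 + |X|), which is stable for silent windows.
  Framing is explicit (stride tricks + `rfft`) so the frame/bin contract
  is pinned; a test cross-checks a frame against a from-scratch windowed
  DFT.
* **PCA**: one frame = one STFT time slice flattened over (channel,
  frequency), 18 × 114 = 2,052 dims, projected to 64 components so the
  feature dimension matches the attention width.  The basis is the SVD of
  the mean-centered training frames; for tall matrices the top-k factors
  come from the eigendecomposition of the 2052 × 2052 scatter matrix
  (algebraically identical, much cheaper).  The basis stores the retained
  singular values *and* the total centered energy, so explained-variance
  ratios and the Eckart–Young tail identity are exact; component signs
  are fixed by the largest-magnitude loading for determinism.  During
  cross-validation the basis is refit per fold on training frames only
  (optionally a seeded subsample, default cap 6,000 frames, which bounds
  the decomposition cost without touching test data).

## Model

Input: a 127-step sequence of 64-dim feature vectors.

| stage | shape | parameters |
|---|---|---|
| 3 parallel conv branches, kernels 7/5/3, 4 ch each, ReLU | 12 × 127 | 3,852 |
| quantized dilated conv, k=3, d=2, 12→64 ch | 64 × 127 | 2,368 |
| layer norm (per time step, over channels) | 127 × 64 | 128 |
| 4-head self-attention, width 64 (d_k = 16) | 127 × 64 | 16,640 |
| mean pool + linear head | 2 | 130 |
| **total** | | **23,118** |

* Quantization is uniform mid-tread fake quantization with per-tensor
  step Δ = 2·max|x|/2ⁿ, n = 8 by default, applied to the dilated layer's
  input activations and weights only (the pairing the reference design prescribes); if
  max|x| = 0 the step defaults to 1 so silent tensors quantize to
  themselves.  Backward passes use straight-through gradients (the
  quantizer is the identity in the backward graph); the adaptive step
  keeps every value inside the representable range, so no clipping mask
  is needed.  A `fake_quant` switch disables quantization, giving the
  full-precision ablation and a smooth network for exact
  finite-difference gradient checks.
* The attention head geometry resolves a genuine ambiguity in the
  reference description of the architecture (4 heads "of dimension 64" alongside a 64-wide
  stream and a 24.5k parameter budget): per-head width 64 would require a
  256-wide concat and break the budget, so the standard convention —
  total width 64, 4 heads of 16 — is used.
* Layer order (branches → quantized dilated conv → layer norm →
  attention → pool → head) is a reconstruction; the reference description
  names the components but not their sequence.  ReLU activations, "same"
  zero padding and biases everywhere are conventional defaults.
* The parameter budget (≤ 24,506) is enforced as an invariant and
  checked by brute-force enumeration of every weight tensor, not by a
  closed-form count.

## Training and evaluation

* Adam (lr 10⁻³, β = 0.9/0.999), batch 32, cross-entropy, 30 epochs by
  default; all randomness (init, shuffling) derives from the train-config
  seed, so a fixed seed reproduces loss curves and final weights exactly
  on one BLAS thread.
* Features are rescaled by the inverse global RMS of the training
  sequences before training (stored with the model); PCA projections are
  dominated by the first components and this keeps the quantized stream
  in a well-conditioned range.
* Cross-validation is stratified at window level by default (the common
  protocol in this literature); recording-grouped splitting
  (`group_by_recording`) is available and recommended against
  within-recording leakage when enough recordings exist.  Folds are
  disjoint and covering; single-class splits raise instead of silently
  degrading.
* AUC uses midpoint tie handling and equals the Mann–Whitney concordance
  probability (asserted against a brute-force pairwise oracle to 1e-9).
  Undefined ratios (e.g. sensitivity with no positive truths) are NaN
  with an explicit flag.

## Problem sizes

The packaged benchmark is 8 recordings × 704 s (18 channels, 256 Hz),
two 112-s seizures each at gain 5, yielding 43 windows per class after
stride-16 oversampling — the smallest layout giving ≥ 40 windows per
class, chosen so a full 5-fold evaluation plus its permutation null runs
in a couple of minutes on one core.  The end-to-end checks train for 20
epochs per fold; the separable benchmark converges well before that.

## Known limitations

* Quantization is simulated in floating point (fake quantization); there
  are no integer-only inference kernels.
* The EDF writer emits plain EDF (16-bit, 1-s records, integer sampling
  rates, whole-second durations); EDF+ event channels and BDF are out of
  scope.  Reading goes through `mne`, which handles the wider dialect
  range.
* No artifact rejection, ICA, re-referencing, or preictal-horizon
  ("forecasting") labeling; the task implemented is ictal *detection*.
* The heuristic overlap oversampler is a documented stand-in for a
  technique the reference design names but never specifies.
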