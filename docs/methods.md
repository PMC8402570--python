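# Methods

This note records what the package computes, the parameter choices and
numerical decisions behind it, and the scope of the synthetic generator.

## Study design being modeled

Two participant pools perform three visual sustained-attention tasks:

| task    | pool  | trials/session | sessions | critical events | stimulus interval |
|---------|-------|----------------|----------|-----------------|-------------------|
| atc     | exp 1 (14) | 1,600     | 1        | 3.3%            | 2.0 s fixed       |
| oddball | exp 1 (14) | 360       | 1        | 10%             | 2.0 s fixed       |
| line    | exp 2 (29) | 1,600     | 2        | 10%             | 1.3–1.7 s uniform |

Three of the 29 experiment-2 participants (the tail of the roster) have
only one line session. Epochs are 1 s, 64 channels, 250 Hz.

## Synthetic generator

**Behavior.** Per session, the expected proportion correct declines and
the expected correct response time rises linearly over the four time bins
(`pc_start + b·pc_slope`, `rt_start_s + b·rt_slope_s`, bin index b =
0…3), with Gaussian per-participant jitter on all four trajectory
parameters. Critical events are Bernoulli at the task's critical
fraction; response times are Gaussian around the bin mean (floored at
50 ms) and defined only for trials with a response.

**EEG.** Each epoch is a sum over the five clinical bands of band-limited
processes plus white broadband noise. A band's process is synthesized in
the frequency domain as equal-power random-phase harmonics on the 1 Hz
rfft grid inside the half-open interval `[f_lo, f_hi)`, which makes the
per-band time-domain variance *exact* — every band power has a closed
form usable as a test oracle. The alpha-band variance is multiplied by
`1 + δ·f`, where `f ∈ [0, 1]` is the trial's elapsed fraction of the
session and δ (`alpha_fatigue_gain`, default 1.0) is a free simulation
parameter; the implied bin-4/bin-1 alpha-power ratio has the closed form
`(1 + δ·E[f | bin 4]) / (1 + δ·E[f | bin 1])` ≈ `(1+0.875δ)/(1+0.125δ)`
(≈ 1.667 at δ = 1). Log-normal per-participant channel gains are shared
across bands, so log band *ratios* cancel the participant factor — this
is what makes cross-participant transfer learnable. Per-task log-normal
band offsets add task differences.

**Scope.** The generator emulates the *structure* of the study (pools,
tasks, trial counts, declining performance, rising alpha), not real EEG:
no 1/f background, no artifacts, no electrode geometry, channels are
statistically exchangeable, and δ is not fit to any real effect size.

## Scoring and labeling

Per participant–task–session, trials are split into four contiguous bins
(remainder to the earliest bins). Bin accuracy is
`(hits + correct rejections) / trials`; bin RT is the mean response time
over hits. Both are z-scored across the session's four bins with sample
SD (ddof = 1), and `BIS = z(PC) − z(RT)`. A least-squares slope of BIS
over bins summarizes the session; a negative slope is a vigilance
decrement. Epochs from bin 1 are labeled attentive (0), bin 4 decrement
(1); bins 2–3 stay unlabeled. Zero-variance PC or RT across bins zeroes
the corresponding z-term with a warning; a bin with no hits has
undefined RT (NaN).

## Spectral features

Mean Morlet wavelet power per channel and band (delta 2–4, theta 4–7,
alpha 8–12, beta 13–29, gamma 33–80 Hz) at 1 Hz wavelet steps:
320 features per epoch. Features are `log10(x + 1e−12)`-transformed and
z-scored per feature, with statistics fitted on the training fold only.

Numerical choices (all verified in the test suite):

* The transform is evaluated spectrally: each epoch is reflection-padded
  to three times its length, FFT'd once, and multiplied by one-sided
  Gaussian kernels with unit power gain at the center frequency; the
  time-averaged squared magnitude is obtained via Parseval's theorem
  over the padded support. This is ~7× faster than per-wavelet inverse
  transforms and agrees with exact center-window extraction to within a
  few percent in the slowest band.
* The wavelet's spectral SD is `σ_f = max(0.6 Hz, f/10)` — constant
  0.6 Hz resolution up to 6 Hz, 10 cycles above. Conventional 3–7-cycle
  rules give multi-Hz bandwidths at low frequencies, which bleed delta
  into theta and theta into alpha; the resolution floor keeps adjacent
  clinical bands separable (measured single-band containment ≥ 0.90 in
  every band, the invariant the test suite enforces).
* Wavelet grids are half-open `[f_lo, f_hi)` because adjacent bands
  share edge frequencies; each grid frequency belongs to exactly one
  band.

## Models

No deep-learning framework is used; `vigil.nn` is a small float32 numpy
sequential-network engine (dense, dilated causal Conv1D, batch norm,
ReLU, inverted element- and channel-wise dropout, average pooling,
nearest-neighbor upsampling, residual TCN units, Adam, BCE-with-logits
and MSE losses) with manual backpropagation, gradient-checked in the
tests.

* **MLPNN** (spectral): 320 → 250 → 200 → 150 → 1, ReLU + dropout 0.5
  after each hidden layer, Adam at 1e−5, 300 epochs, binary
  cross-entropy. Parameter count 160,751
  (320·250+250 + 250·200+200 + 200·150+150 + 150·1+1).
* **TCN** (raw sequence): residual units at dilations (1, 2, 4, 8, 16,
  32) repeated over 2 blocks, kernel 2 (best classifier uses kernel 4),
  10 filters, batch norm, dropout and channel-wise "recurrent-style"
  dropout 0.5, then a kernel-1 Conv1D with 4 filters (ReLU) and a
  sigmoid unit; Adam at 1e−4, 100 epochs. Receptive field =
  kernel · blocks · final dilation (2·2·32 = 128, 4·2·32 = 256,
  2·1·8 = 16, 2·2·8 = 32).
* **TCN-AE**: encoder = TCN (kernel 2, 2 blocks, 36 filters, no
  dropout) → kernel-1 Conv1D to L latent filters (ReLU) → temporal
  average pool 5, giving a 50 × L latent for 250-sample epochs; decoder
  = nearest-neighbor upsample ×5 → TCN → kernel-1 Conv1D back to 64
  channels, with **no activations** anywhere in the decoder. The AE is
  trained for reconstruction (MSE, Adam at 1e−4, 50 epochs) on
  channel-standardized epochs; the encoder is then frozen (bit-exact,
  asserted in tests) and its flattened latent feeds a two-hidden-layer
  ReLU + dropout classifier.

Initialization: dense layers and standalone classifier convolutions use
He-uniform. Convolutions inside residual units use small-normal
(σ = 0.01) weights, and the autoencoder's standalone kernel-1
convolutions σ = 0.05: with a linear decoder, variance-preserving
initialization compounds multiplicatively through the residual stack and
the first reconstruction loss explodes; near-identity initialization
keeps the initial loss at the signal scale. The latent width L and the
minibatch size are free hyperparameters (they were search dimensions in
the original design); reconstruction quality improves with both more
latent capacity and more optimizer steps per epoch.

## Cross-validation

Leave-2-participants-out, cross-task: the experiment-1 pool is split
into disjoint validation pairs by a seeded permutation (7 folds at full
scale). Per fold, training uses the other experiment-1 participants'
ATC epochs plus every experiment-2 line epoch; validation uses the
held-out pair's oddball epochs only. Feature standardization (spectral
z-scoring; channel standardization for raw-sequence models) is fitted on
the fold's training epochs. Structural leakage checks (validation
participants or task in training, train/validation overlap) abort the
run. At full scale each fold has exactly 53,600 training and 360
validation labeled epochs. Pooled metrics are computed over the
concatenated validation predictions of all folds (the alternative —
averaging per-fold metrics — is equivalent here up to fold-size
weighting and is not used).

## Statistics

Binomial accuracy CIs use the Agresti-Coull adjustment at z = 1.959964
(x̃ = x + z²/2, ñ = n + z²), clipped to [0, 1]; a model is significantly
better than chance iff the interval lies strictly above 0.5. Display
rounding is half-up at 2 decimals. Two models on the same validation
set are compared with an unpooled Wald interval on the difference of
proportions and McNemar's test `(b − c)²/(b + c)` (no continuity
correction by default) on the discordant predictions. Balanced accuracy
and AUROC come from scikit-learn, cross-checked in the tests against
per-class recall averaging and brute-force pair counting.

## Limitations

* The generator is a structural emulation; absolute accuracies obtained
  on it say nothing about real-EEG performance, and its default δ = 1.0
  produces a much stronger class signal than real fatigue data.
* The numpy engine trains on one CPU; full-scale (53,600 epochs/fold)
  deep-model training is out of desk-scale budgets, so model-training
  analyses run at the reduced desk scale while the full-scale replica is
  used for structural accounting.
* EDF ingest/export is not provided; datasets round-trip through
  `.npy` + CSV + JSON sidecar.
* The spectral cycle rule deviates from common fixed-cycle conventions
  (see above) to satisfy band separability at 1 Hz resolution.
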