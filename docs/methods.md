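# Methods

## Problem setting

A ten-sensor MOS array measures the headspace of a liquid sample over a
364 s exposure-and-recovery cycle at 100 Hz. Each measurement is a panel of
response curves; the classification target is the sample's brand/class.
Because MOS sensors are cross-sensitive, class identity lives in the joint
pattern of responses across the panel rather than in any single sensor.

## Sparse auto-encoder

One layer maps x ∈ [0,1]^m to y = S(Wx + b) (n hidden units) and
reconstructs z = S(Wᵀy + b′) with the *same* matrix (tied weights). The cost
is the batch-mean squared reconstruction error (with the ½ factor, summed
over input dimensions), plus weight decay (λ/2)‖W‖², plus the KL sparsity
penalty β Σⱼ KL(ρ‖ρ̂ⱼ) with ρ̂ⱼ the batch-mean activation of unit j.
Interpretation notes frozen into the implementation:

- The reconstruction term averages over **samples** and sums over input
  dimensions — the standard reading when one symbol does double duty as
  both the input-node count and the sample count.
- Tied weights are taken literally: the gradient of W sums the encode-path
  and decode-path contributions. The finite-difference suite checks this for
  every (β, λ) ∈ {0, >0}².
- ρ̂ⱼ is computed per mini-batch, because that is the quantity the gradient
  needs at update time; the logged diagnostics use the full-data ρ̂.
- ρ̂ is clamped to [1e−12, 1−1e−12] before the logs, so the KL term is
  always finite even when a sigmoid saturates in float64.

Training is plain mini-batch SGD (no momentum or adaptive step): per epoch a
seeded shuffle, mini-batches of 10, one step per batch at rate ε₁ = 0.1.
Weights initialize uniform on ±4√(6/(m+n)) — the sigmoid-suited Glorot
scale — with zero biases, from a seeded generator, so training is bitwise
reproducible.

## Stacking, head, fine-tuning

Greedy layer-wise pretraining trains layer 1 on the scaled input vectors and
layer i>1 on layer i−1's codes. The encode halves are then copied (decoder
biases discarded) into a classifier with a softmax output layer initialized
uniform ±0.01. Fine-tuning updates **all** layers by mini-batch SGD at rate
ε₂ = 1. The loss is softmax cross-entropy by default — the standard pairing
with a softmax head — with an optional `loss="mse"` switch (squared error
between one-hot targets and probabilities, back-propagated through the
softmax Jacobian); the MSE is always logged per epoch either way, as it is
the conventional convergence diagnostic for this architecture. Prediction is
the arg-max probability with ties broken toward the lowest class index.
The full-scale geometry is 3640–200–100–7 with ρ = 0.01, β = 0.1; λ has no
established reference value, so the default is 1e−4 — small enough that the
decay term cannot dominate the β = 0.1 sparsity term at these scales, while
still regularizing the 3640×200 first layer.

## Input scaling

A sigmoid decoder can only reconstruct values in (0,1), so inputs are mapped
coordinate-wise to [0,1] by an affine min–max scaler fitted on the training
folds only; held-out values are clipped into [0,1] and coordinates constant
in training map to 0.5. This is a deliberate preprocessing step: raw
conductivities are unbounded and cannot be sigmoid-reconstruction targets.

## Traditional arms

- **Method 1**: wavelet denoising (db4, level 4, soft universal threshold
  σ̂√(2 log n), σ̂ from the MAD of the finest detail band), conductivity
  normalization (divide by the mean of the first 5 s — the pre-exposure
  baseline), then ten descriptors per curve: time of maximum, RMS,
  arithmetic/geometric/harmonic means, max first derivative and its time,
  average differential (mean first difference), trapezoid integral up to the
  maximum, and mean curvature |y″|/(1+y′²)^{3/2} averaged over interior
  points. The descriptor formulas are standard readings, declared here as
  the package's definitions; geometric/harmonic means guard non-positive
  curves by shifting to min+1e−9. Derivatives are central differences with
  one-sided edges, scaled by the sampling interval. 100 columns for a
  ten-sensor panel, z-scored (training-fold fit), reduced to 20 by KECA.
- **Method 2**: Savitzky–Golay (window 51, order 3 at 100 Hz), five
  descriptors (max value, max/min first derivative, response at the
  first-derivative max, max second derivative) → 50 columns → PCA to 19.
- **KECA**: Gaussian kernel K with the median-pairwise-distance width by
  default; eigenpairs scored by (√λᵢ eᵢᵀ1)² and the top-k by *entropy
  contribution* kept. Training projections are rows of √λᵢ eᵢ; out-of-sample
  points use the Nyström extension K(x, X_train) E Λ^{−1/2}, which
  reproduces the training projection exactly on training points. Negative
  eigenvalues from round-off are clamped to zero and never selected.
- **Classifiers**: an RBF SVM (C = 1, one-vs-one) and a BPNN that reuses the
  stacked-network machinery with randomly initialized hidden layers.

`assemble_features` returns raw descriptors; z-scoring is a separate
fit/apply pair so cross-validation can fit it on training folds only.

## Synthetic data generator

The generator emulates the acquisition geometry — 7 classes × 30 replicates
× 10 sensors, 364 s at 100 Hz — with a rise–plateau–decay kernel:
baseline 0.5 until injection at t = 20 s, saturating exponential rise
(τ_rise = 15 s) to the peak at t = 80 s, then slow exponential recovery
(τ_decay = 120 s), continuous at the peak. Class identity is a per-sensor
peak-amplitude fingerprint, amplitude_scale × (1 + δ·u) with u ~ U(−1,1)
i.i.d. per (class, sensor) and δ = 0.6 by default; kinetics are shared
across classes, so classifiers must learn the amplitude pattern. Additive
i.i.d. Gaussian noise (σ = 0.02) and a per-curve linear drift
(slope sd 5e−4 /s) complete the model. δ = 0.6 and σ = 0.02 were chosen once
as a clearly-separable regime a bench panel of distinct spirit brands would
plausibly produce; δ = 0 gives the null regime where any classifier must sit
at chance.

What the generator does **not** emulate: sensor-specific drift and recovery
kinetics, humidity/temperature covariates, adsorption nonlinearity,
inter-replicate kinetic variation, and the unknown real inter-class effect
sizes. Passing tests therefore demonstrate that the pipelines are correct
and leakage-free and that the SSAE can learn amplitude-pattern features —
not that any accuracy measured here transfers to real instrument data.
A `rate_hz=1.0` shortcut generates directly at the analysis rate, avoiding
the 100× memory/time cost of full-rate generation; the full-rate path is
exercised where the decimation geometry itself is under test.

## Evaluation protocol

Stratified ten-fold cross-validation (seeded shuffle; per-class counts
within ±1 across folds; an unstratified mode exists). Every fitted transform
— unit scaler, z-scorer, PCA/KECA, pretraining, fine-tuning — is refit per
fold on the training folds only. The dispersion statistic across folds,
reported as the "interval of confidence", is the standard error of the mean
(sd/√k) by default with a Student-t 95% half-width option; SEM matches the
magnitude conventionally reported for this quantity but no claim is made
that it matches any particular external definition. A shuffled-label mode
permutes labels once before splitting; with no leakage the resulting
accuracy must lie within 3 binomial standard deviations of chance, and the
test suite enforces this for every pipeline arm.

## Numerical and design choices

- Decimation (100 Hz → 1 Hz) is pure phase-0 point sampling, not averaging.
- Gradient checks use symmetric relative error against central differences
  at h = 1e−5, with a 1e−6 acceptance bound.
- Batch size defaults to 10 for both pretraining and fine-tuning.
- One global seed fans out to per-stage seeds by fixed offsets, so each
  stage is independently reproducible.
- Test and acceptance runs use a scaled-down network (hidden 40/20,
  30 epochs) — the problem sizes reported by `scripts/acceptance.py` — since
  the synthetic classes are separable well below the full 200/100 widths.

## Known limitations

- No momentum/adaptive optimizers, dropout, batch norm, or untied weights.
- The BPNN arms can be sensitive to the ε₂ = 1 learning rate on poorly
  scaled features; features are always z-scored or unit-scaled first.
- KECA's out-of-sample projection assumes the training kernel basis spans
  new points adequately (Nyström approximation).
- Real-data accuracies depend on instrument effects the simulator omits;
  the synthetic benchmarks are correctness and capability floors, not
  performance claims.
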