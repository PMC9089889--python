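# Methods

`channelsynth` trains a generative adversarial network to synthesise
two-row single-channel recordings — a current trace and a synchronous
idealised state label — and evaluates the synthetic output with
distributional, kinetic and manifold-level statistics. This note records
the model, its parameters, the numerical choices, and the limitations.

## 1. Gating simulator (`channelsynth.markov`)

Channel gating is a continuous-time Markov chain on states
`s_1 … s_n` with generator matrix `Q` (off-diagonal `q_ij ≥ 0` = transition
rate from `s_i` to `s_j` in s⁻¹; rows sum to zero). Each state carries an
integer *open count*; the noiseless current is

```
I(t) = baseline + open_count(s(t)) · i_u
```

with unitary current `i_u` in pA. The label row is the open count itself,
so label and current are synchronous by construction — this is the paired
structure the GAN is trained to reproduce.

Simulation is exact (Gillespie): the jump chain is drawn from the
embedded-chain transition probabilities with exponential holding times
`Exp(−q_ii)`, started from the stationary distribution `π` (solved from
`πQ = 0, Σπ = 1` via the null space of `Qᵀ`; a strong-connectivity check
rejects reducible schemes by name). The piecewise-constant state path is
then snapped to the uniform sample grid with `searchsorted` — no
event-to-sample rounding error accumulates. Gaussian noise of standard
deviation `noise_sd` (pA, amplifier-referred, i.e. added **before**
filtering) and a causal 4-pole Butterworth low-pass complete the raw row.

Defaults (fixture choices, not a measured channel): two-state C⇌O scheme
with opening rate 50 s⁻¹, closing rate 100 s⁻¹ (open probability 1/3,
mean open dwell 10 ms), unitary current −5 pA, noise 1 pA, 5 kHz sampling,
1 kHz cutoff. Validation enforces `sample_rate > 2 × filter_cutoff` and a
minimum duration of 10 fastest time constants.

## 2. Preprocessing (`channelsynth.signal_io`)

* **Robust scaling.** The current row is centred on its median and scaled
  by its IQR — outlier-resistant, so brief large excursions do not compress
  the informative range. The label row is mapped affinely so that the
  smallest level → −1 and the largest → +1 (a single-level record maps to
  −1 and is flagged `degenerate_label`); this matches the generator's
  `tanh` output range. Both transforms are exactly invertible; decoded
  labels are snapped to the nearest encoded level, ties to the lower level.
* **Windowing.** A record of length `L` yields `N = ⌊(L−W)/stride⌋ + 1`
  contiguous `2×W` windows (default `W = 1280`, stride `W/2`); no padding,
  a trailing partial window is dropped.
* **Augmentation.** Optional Gaussian jitter on the scaled current row
  only, with SD expressed as a fraction (default 10⁻³) of that row's
  peak-to-peak range; labels are never perturbed.
* **Edge cropping.** Generated windows are cropped by a fraction (default
  5 %) per side before decoding, discarding boundary artefacts from the
  transposed convolutions.
* **I/O.** CSV (`time_index,current_pA,label` plus a
  `# sample_rate_hz=…` comment line) and HDF5; both round-trip exactly.

## 3. GAN (`channelsynth.gan`, `channelsynth.nn`)

A one-dimensional DC-GAN implemented directly in NumPy (no deep-learning
framework is assumed), with hand-derived backpropagation:

* **Generator:** latent vector (default dim 128, `N(0,1)`) → dense →
  reshape to `64ch × W/8` → three transposed-convolution stages
  (kernel 4, stride 2, channels 64→32→16→2) with batch-norm and
  LeakyReLU(0.2), `tanh` output → a `2×W` window. An image-shaped latent
  (`latent_shape="image"`) is available as an option.
* **Discriminator:** three strided convolutions (2→16→32→64, kernel 4,
  stride 2) with LeakyReLU(0.2) and dropout 0.3 after the hidden
  convolutions, then a dense layer to a single logit.
* **Losses:** binary cross-entropy. The discriminator minimises
  `BCE(1, D(x)) + BCE(0, D(G(z)))`; the generator uses the
  **non-saturating** form `BCE(1, D(G(z)))`, which keeps gradients alive
  early in training when the discriminator wins easily. Gradients are
  taken in logit space (`(p − y)/B`), which is both cheaper and numerically
  stable.
* **Optimisation:** Adam, learning rate 10⁻⁴, β₁ = 0.5 (the standard
  DC-GAN setting; β₁ = 0.9 is too much momentum for adversarial
  dynamics), batch 64, alternating single D and G steps per batch, with
  per-epoch reshuffling and inline augmentation of the real batch.
* **Reproducibility:** all randomness (init, dropout, latent draws,
  shuffling) descends from one `SeedSequence`, so identical seeds give
  bit-identical training runs. Checkpoints store parameters, batch-norm
  running statistics, Adam state, the architecture spec and the scaler;
  training can resume exactly, and `generate` accepts either a checkpoint
  directory or an in-memory generator.

Convolutions are evaluated as BLAS matrix products (one GEMM per kernel
offset) rather than explicit loops; a 200-epoch run at `W = 64` takes about
30 s on one CPU core.

## 4. Fidelity metrics (`channelsynth.metrics`)

* **MMD.** Unbiased squared maximum mean discrepancy with a Gaussian
  kernel, diagonal terms omitted from the within-group sums; bandwidth by
  the median heuristic on the pooled sample unless given. Windows are
  compared as flattened `2W`-vectors. Requires ≥ 2 samples per group.
* **DTW.** Exact dynamic-programming DTW (absolute or squared local cost),
  numba-accelerated with a pure-Python fallback, plus a coarsen-recurse-
  refine approximation (radius parameter; radius ≥ max(N,M) reproduces the
  exact value bit-for-bit). Batch comparison averages DTW over a seeded
  random sample of window pairs on the current row.
* **Amplitude histograms.** All-points histograms (Freedman–Diaconis bins
  by default); the distance between two batches is the histogram
  intersection distance `1 − Σ min(p_i, q_i)` on shared pooled bin edges.
  A peak counter (smoothed histogram + prominence threshold) is used to
  check that generated data keep the two-level structure.

## 5. Dwell-time kinetics (`channelsynth.kinetics`)

The label row is run-length encoded into sojourns; all conducting levels
(label ≥ 1) are aggregated as "open". The first and last sojourns are
censored (their true lengths are unknown) and dropped. Dwell distributions
are fitted as mixtures of exponentials by EM with multistart (quantile
initialisation plus log-normal perturbations); `K = 1` uses the closed-form
MLE (the sample mean). The EM implementation asserts per-iteration
likelihood monotonicity and merges near-duplicate time constants. Model
order is chosen by BIC with `2K − 1` free parameters. A √density
log-binned histogram helper is provided for plotting only.

## 6. Manifold evaluation (`channelsynth.manifold`)

Two window sets are embedded **jointly** (never separately — independent
embeddings are not comparable) into 2-D with t-SNE or UMAP, seeded for
reproducibility; perplexity / `n_neighbors` are capped for small inputs,
and ≥ 10 windows per group are required. Separability is tested by
permutation: the statistic is the mean out-of-fold accuracy of a linear
discriminant (pooled covariance with ridge 10⁻⁹) over 5 folds; group
labels are permuted ≥ 1000 times and the p-value uses the add-one rule
`(1 + #{null ≥ observed}) / (1 + n_permutations)`, so the smallest
attainable p is `1/(n_permutations + 1)` and the test is exact-level by
construction. Degenerate (constant) embeddings return accuracy 0.5, p = 1.

A small p means the synthetic data are *distinguishable* from the real
data in the embedding — for a generator, large p is the desirable outcome.

## 7. Problem sizes

The shipped examples, tests and acceptance script use window length 64,
batch size 32, 200 training epochs and seed records of a few seconds —
sizes chosen so the full pipeline runs in minutes on one CPU core. These
are this package's own demonstration sizes; the architecture accepts any
window length divisible by 8.

## 8. Limitations

* **No missed-event correction.** Dwells shorter than the sample interval
  or suppressed by the low-pass filter are lost, biasing fitted fast time
  constants upward; classical missed-event corrections are not implemented.
* **Finite windows attenuate long dwells.** Sojourns longer than a window
  cannot be represented in windowed training data, so generated kinetics
  under-represent the long-dwell tail relative to the seed record.
* **Label decoding is level-snapping,** not a kinetic idealisation: a
  generator that outputs intermediate label values will be snapped to the
  nearest trained level, ties to the lower level.
* **Single-channel records only.** Superimposed openings of multiple
  channels in one patch are not modelled.
* **Training stability.** Plain alternating BCE GAN training can collapse
  for unlucky seeds or aggressive learning rates; the trainer aborts on
  non-finite losses and keeps a best-held-out-MMD checkpoint alongside the
  latest one, but no gradient penalty or spectral normalisation is used.
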