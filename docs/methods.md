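# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the `swctnet` package.

## Problem setting

Wearable shoulder-rehabilitation systems record two complementary
modalities: an inertial measurement unit (IMU: tri-axial accelerometer,
gyroscope and magnetometer at 200 Hz) captures joint kinematics, and
surface electromyography (sEMG: 4–5 skin electrodes at 2000 Hz) captures
muscle activation. sEMG is informative but impractical at home
(electrode placement, skin preparation), so the package implements a
cross-modal pipeline: learn, from sessions where both modalities were
recorded, to predict muscle-activation features and EMG feature
sequences from IMU alone, and to classify the movement being performed.

## Preprocessing

- **Coordinate transform.** Sensor-frame triads are rotated into the
  global frame per sample, `g_global = R · g_local`. Rotation matrices
  are an *input* (from the sensor's own fusion, or the synthetic
  generator's ground truth); the package deliberately does not estimate
  orientation with a Kalman-type filter, so the transform is exactly
  testable (norm preservation to 1e-9).
- **Euler angles.** Roll `φ = atan2(a_y, a_z)`, pitch
  `θ = arcsin(−a_x/g)` with `g = 9.80665 m/s²`, yaw `ψ = atan2(m_y, m_x)`.
  Four-quadrant `atan2` replaces the plain arctangent, which loses
  quadrant information. The arcsin argument is clipped to [−1, 1] with
  tolerance 1e-6; samples beyond tolerance become NaN and are counted.
  The yaw estimate uses only the horizontal magnetometer components with
  *no tilt compensation* — it is exact only for a level sensor, a known
  limitation of this estimator.
- **Band-pass filtering.** Order-4 Butterworth band-pass, 10–500 Hz,
  designed from the analog prototype
  `|H(jω)|² = 1 / (1 + (ω/ω_c)^(2n))` by bilinear transform with
  pre-warped edges (scipy's `butter`), applied forward–backward
  (`sosfiltfilt`). Zero-phase application preserves EMG–IMU temporal
  alignment at the cost of doubling the effective order; the passband
  contract is tested on tone levels, not on filter coefficients.
- **Downsampling.** Non-overlapping block means with factor M = 10
  (2000 → 200 Hz); a trailing partial block is dropped. EMG is filtered
  at its native rate *before* downsampling (anti-aliasing ordering).
  After 10× downsampling the Nyquist frequency is 100 Hz while EMG
  energy extends to ~150 Hz, so all spectral features are computed on
  the native-rate signal before downsampling.
- **Alignment.** Greedy one-pass timestamp matching: a pair (i, j) is
  accepted when `|t_EMG[i] − t_IMU[j]| < δt` with δt = 5 ms, each sample
  used at most once; unmatched samples are discarded and counted. Note
  that a shift equal to a whole number of sample periods re-aligns at a
  lag — greedy matching pairs what *can* be paired.

## EMG window features

Six per-channel features per 200 ms window (400 samples at 2000 Hz):

- RMS `√(Σx²/N)` and MAV `Σ|x|/N` (amplitude/intensity),
- ZC: count of adjacent pairs with `x[n]·x[n+1] < 0` and
  `|x[n] − x[n+1]| ≥ ε` (frequency proxy). The literature sometimes
  prints a near-zero-product rule (`|x[n]·x[n+1]| < ε`); that literal
  variant is available as `zc_mode="literal"` but contradicts the
  purpose of counting *crossings*, so the sign-change rule is the
  default. ε defaults to 1e-4 of the window's peak amplitude.
- WL `Σ|x[n+1] − x[n]|` (waveform complexity),
- SSC: count of interior samples where the slope changes sign (strict
  inequality),
- MPF: spectral centroid `Σ f·P(f) / Σ P(f)` of a Welch estimate
  (Hann window, segment length N/4, 50 % overlap, density scaling, no
  detrending; the integral of the density matches the mean-square signal
  power within 5 %). MPF is defined as 0 for an all-zero window.

## Dataset construction

Sliding windows of L = 200 ms with step S = 50 ms (40 IMU points; the
EMG window spans the same time at the native rate, 400 points).
Splitting is 70/20/10 per movement by the largest-remainder rule,
stratified by movement and by group (healthy/injured), at **repetition
granularity**: all windows of one repetition land in the same subset.
This simultaneously satisfies "each repetition is an independent sample"
and "overlapping windows must not straddle subsets". Channel-wise
z-score statistics are estimated on the training subset only (σ floored
at 1e-8 for constant channels) and applied to all subsets.

## SWCTNet architecture

Input: a `(N_ch × N_L)` window (9 IMU channels × 40 steps by default).

1. **SW-CNN block.** The input is partitioned into overlapping
   sub-windows (`L_win = 16`, step 8 → k = 4 windows), each passed
   through a same-padded 1-D convolution (H = 16 filters, kernel 5,
   ELU), BatchNorm over the batch, **WindowNorm** (per-window
   standardization along time with learnable per-channel affine and a
   σ floor of 1e-5), mix pooling
   `ratio·maxpool + (1−ratio)·avgpool` (ratio 0.5, kernel = stride = 2)
   and dropout 0.5. Output `X_cnn ∈ R^(k×H×L)` with L = 8.
2. **CTAT block.** `X_cnn` is flattened to `X_flat ∈ R^((k·H)×L)`, a
   learnable positional encoding (init N(0, 0.02²)) is added, and two
   multi-head attention paths run in parallel:
   - the **channel path** treats the k·H rows as tokens (key dim
     `d_c = ⌈N_ch/4⌉`),
   - the **time path** treats the L columns as tokens (key dim
     `d_t = ⌈L/4⌉`).
   As printed, the two attention matrices have incompatible shapes
   (`L×L` vs `(kH)×(kH)`) and cannot be summed; here each path attends
   along its own axis, producing attended maps of the common shape
   `(k·H)×L`, and a learnable sigmoid gate fuses the attended
   **outputs**: `fused = λ̄·out_c + (1−λ̄)·out_t`. The gate is one
   scalar per head, `λ_h = sigmoid(W_g·[s_c,h; s_t,h] + b_g)`, where the
   summaries `s` are the batch-mean of each attention row's maximum (a
   peakedness statistic; the plain mean of a row-stochastic matrix is
   constant and carries no signal). Summaries are treated as
   non-differentiated statistics — gradients reach `W_g` and both path
   outputs directly. Since head outputs are concatenated before the
   output projection, fusion uses the mean gate λ̄ over heads. Standard
   value projections (dimension `token_dim / n_heads` per head) are
   used; the residual and per-token LayerNorm follow:
   `X_fused = LayerNorm(X_attn + X_flat)`. Two CTAT layers, 2 heads.
3. **Task heads.** Features are mean-pooled over the time axis into a
   k·H-dimensional vector.
   - *Classification*: dropout 0.5, linear map, softmax.
   - *Regression*: dropout 0.5, linear map to the 30 targets
     (5 EMG channels × 6 features, z-scored with training statistics).
   - *Generation*: an autoregressive cross-attention decoder. At each
     step the previous output (or a learned start token) is embedded as
     a query that attends over the encoder memory's time tokens; a
     two-layer head (tanh, dropout 0.7) maps [context; query] to the
     next feature vector. Teacher forcing during training, free-running
     at inference. The memory may be a single fused map or a per-step
     sequence of maps (used for per-repetition sequences).

A max-norm constraint of 0.25 is projected onto the head-layer weight
rows after every optimizer step. Dropout uses inverted scaling, so
inference needs no rescaling; a spatial variant (dropping whole
channels) is available behind a flag. All initialization and dropout
randomness derives from the seed in `ModelConfig`.

Filter count (16), head count (2), layer count (2), kernel width (5)
and the mix-pooling configuration are package defaults sized for the
desk-scale synthetic benchmarks; all are overridable in `ModelConfig`.

**Ablation variants**: M1 = no conv front end (windows only mix-pooled),
time attention only; M2 = + SW-CNN; M3 = + channel path and gate;
M4 = full. Parameter counts order M1 < {M2, M3} < M4.

### Why a bespoke autodiff engine

The network is implemented on a small numpy reverse-mode automatic
differentiation engine written for this package (`autodiff.py`):
tensors record their parents and backward closures; softmax/log-softmax
are fused ops; 1-D convolution is a dedicated op via sliding-window
views. Gradients are verified against central finite differences for
every op. Training uses Adam (default lr 1e-3, batch 32) with early
stopping on validation loss (patience 10 by default) and
best-checkpoint restoration; runs are deterministic under a seed on one
device.

## Evaluation metrics

- Accuracy per class and overall (percent); average accuracy is the
  arithmetic mean over participants when participant ids exist,
  otherwise over classes.
- RMSE `√(Σ(y−ŷ)²/n)`.
- DTW by classic dynamic programming with steps {(1,0),(0,1),(1,1)};
  local distance |a−b| for scalar series, Euclidean for vector series.
  Normalized DTW divides by the sequence length n (the longer one when
  lengths differ); dividing by the optimal warping-path length is
  available via `norm="path"`. The implementation is validated against
  exhaustive enumeration of all monotone warping paths for short
  sequences.

## Synthetic data generator

The generator emulates the recording protocol the pipeline assumes:
three shoulder movements (abduction, forward flexion, internal/external
rotation), 10 repetitions of 5 s with 2 s rest, IMU at 200 Hz, five EMG
channels (Deltoid, Trapezius, Biceps, Triceps, Latissimus) at 2000 Hz.
Benchmarks default to 2 subjects (1 healthy, 1 injured) — a desk-scale
choice so the full train/evaluate cycle runs in minutes on one CPU.

- **Kinematics**: each movement has a primary rotation axis and a
  movement-specific wobble frequency (0.8 / 1.2 / 1.6 Hz) superimposed
  on a smooth sin² raise-and-lower profile, plus small secondary-axis
  motion. The accelerometer reads gravity rotated into the moving frame
  plus a lever-arm motion term and white noise; the gyroscope reads
  Euler-angle rates plus noise (a simplification: true body rates
  differ from Euler rates at large tilt); the magnetometer reads a
  horizontal field rotated by yaw only, consistent with the tilt-free
  yaw estimator, so the noise-free Euler round trip is exact.
- **EMG coupling**: each muscle's activation envelope is a fixed
  gain-weighted mix of the absolute Euler-angle rates, delayed by a
  50 ms electromechanical latency and low-pass smoothed at 5 Hz; the
  carrier is unit-RMS 20–150 Hz band-limited noise. Baseline drift
  (2 µV, 0.3 Hz), 50 Hz line interference (configurable to 60 Hz) and a
  10 µV sensor-noise floor are added; amplitudes are clipped to
  ±1.5 mV. Envelope ∝ |angular velocity| is the simplest mechanism that
  makes EMG features predictable from IMU — which is exactly the
  premise the cross-modal tasks need to be able to demonstrate.
- **Pathology**: the injured variant multiplies the envelope by
  non-stationary jitter (≤3 Hz, ±60 % at severity 1) and injects
  tremor bursts (4–6 Hz, 0.10/s) and amplitude dropouts (0.25/s), plus
  extra white noise, all proportional to severity. Event counts scale
  with session duration so the irregularity is pervasive, as patient
  recordings are described to be. Crucially, pathology alters only the
  EMG — the IMU is unchanged — so patient feature sequences are
  *intrinsically less predictable from IMU*, which is what the
  generation benchmark measures.

What the generator does **not** emulate: real motor-unit physiology,
muscle-specific frequency content, electrode lift-off artifacts,
crosstalk between channels, subject-to-subject anatomical variation, or
day-to-day electrode placement shifts. Passing benchmarks on this data
shows the pipeline is correct and that the architecture can learn
kinematics-coupled activation; it does not certify accuracy on real
patients.

## Benchmark protocols and sizes

- *Classification*: predict the movement class of a single 200 ms
  window; ~5.8 k windows, 8 epochs of Adam. The benchmark is separable
  by design (distinct axes/frequencies), so near-perfect accuracy is
  the expected correct outcome.
- *Regression*: predict all 30 feature targets per window; reported
  quantity is the RMSE of the 5 RMS targets versus the train-mean
  baseline, plus the correlation between predicted RMS and the
  generator's ground-truth envelope RMS.
- *Generation*: per repetition, the sequence of five-channel window RMS
  values (every 4th window → 200 ms effective step, ~24 steps over a
  repetition) is generated autoregressively from the per-step IMU
  windows; scored by normalized DTW against the true sequence,
  aggregated over held-out (validation + test) repetitions per group.
  The decoder is trained with 30 epochs, batch 4, lr 3e-3 — with only
  ~40 training sequences, larger batches give too few updates per epoch
  for the decoder to converge.

## Known limitations

- Window RMS of an amplitude-modulated noise carrier is itself a noisy
  estimate (~25 % relative at 130 Hz bandwidth × 200 ms), which puts a
  floor under the generation DTW for both groups.
- The gyroscope model outputs Euler-angle rates, not body rates.
- The yaw estimate (and hence the generator's magnetometer) ignores
  tilt.
- BatchNorm running statistics make the evaluation-mode loss depend
  slightly on the training batch composition early in training.
- The autodiff engine is float64 and single-threaded beyond BLAS; it is
  sized for the desk-scale benchmarks, not for GPU-scale datasets.
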