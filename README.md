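# swctnet

Cross-modal analysis of wearable IMU and surface-EMG recordings for
shoulder rehabilitation: predict muscle-activation features — and
generate EMG feature sequences — from inertial data alone, and classify
shoulder movements, using SWCTNet, a sliding-window CNN combined with a
channel–time attention transformer.

## Who this is for

Researchers working with paired inertial (IMU, 200 Hz) and surface-EMG
(sEMG, 2000 Hz) recordings who want a complete, testable pipeline: raw
signal preprocessing, classical EMG window features, leakage-free
dataset construction, a multichannel time-series network with three
task heads, the matching evaluation metrics, and a seeded synthetic
generator that emulates a shoulder-movement recording protocol
(3 movements × 10 repetitions of 5 s with 2 s rest) for development and
testing without access to clinical data.

## The model

An input window `X ∈ R^{N_ch×N_L}` passes through three stages:

1. **SW-CNN** — sliding sub-windows `X_win[i] = X[:, iS : iS+L_win]`,
   each processed by a same-padded 1-D convolution with ELU, BatchNorm,
   per-window WindowNorm (standardize along time within the window,
   learnable affine), mix pooling `r·max + (1−r)·avg`, and dropout,
   giving a feature map `X_cnn ∈ R^{k×H×L}`.
2. **CTAT** — `X_cnn` is flattened to `X_flat ∈ R^{(k·H)×L}`, a learned
   positional encoding is added, and two multi-head attention paths run
   in parallel: a *channel* path over the k·H channel tokens
   (`A_c = softmax(Q_c K_cᵀ/√d_c)`, `d_c = ⌈N_ch/4⌉`) and a *time* path
   over the L time steps (`A_t = softmax(Q_t K_tᵀ/√d_t)`). A learnable
   sigmoid gate `λ = sigmoid(W_g[s_c; s_t])` fuses the attended
   outputs, followed by the residual and layer norm
   `X_fused = LayerNorm(X_attn + X_flat)`.
3. **Task head** — softmax classification, linear regression of the six
   EMG window features (RMS, MAV, ZC, WL, SSC, MPF) per channel, or an
   autoregressive decoder `ŷ_t = Decoder(ŷ_{t−1}, X_fused)` for
   sequence generation; head weights carry a 0.25 max-norm constraint.

Everything runs on a small numpy reverse-mode autodiff engine included
in the package (gradients are verified against finite differences in
the test suite); there is no deep-learning framework dependency.
Evaluation uses per-class/overall accuracy, RMSE, and dynamic time
warping normalized by sequence length. See `docs/methods.md` for the
full account, including every documented design decision.

## Worked example

Train the classifier on the default synthetic benchmark and evaluate:

```python
from swctnet import (ModelConfig, ScenarioConfig, SWCTNet, TrainConfig,
                     make_benchmark, train_classifier,
                     evaluate_classifier)
from swctnet.train_eval import classification_arrays

split = make_benchmark("classification", ScenarioConfig(seed=1), split_seed=1)
model = SWCTNet(ModelConfig(seed=1))
train_classifier(model, split, TrainConfig(epochs=8, patience=3, seed=1))
X, y, pid = classification_arrays(split)["test"]
report = evaluate_classifier(model, X, y, pid)
print(report.overall_accuracy, report.per_class_accuracy)
```

```
100.0 {0: 100.0, 1: 100.0, 2: 100.0}
```

The three movement classes (abduction, flexion, rotation) have distinct
rotation axes and oscillation frequencies, so a correctly working model
separates the 582 held-out test windows essentially perfectly; chance
would be 33.3 %. The same `split` carries per-window EMG feature
targets, so the regression task
(`ModelConfig(task="regression", n_targets=30)`) trains on identical
inputs; on held-out windows its RMS predictions reach roughly half the
error of the predict-the-train-mean baseline (0.052 vs 0.107 mV) and
correlate at r ≈ 0.86 with the generator's ground-truth activation
envelope — muscle activation really is being recovered from inertial
data alone, which is the point of the method.

The same pipeline is scriptable from a shell:

```bash
swctnet simulate --seed 7 --out sessions/
swctnet train --task classification --seed 1 --out run/
swctnet evaluate run/checkpoint.npz --seed 1
```

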