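"""The SWCTNet architecture.

Three stages operate on a multichannel time-series input
``X in R^(N_ch x N_L)``:

1. **SW-CNN block** — the sequence is partitioned into overlapping
   sliding windows, each window passes through a same-padded 1-D
   convolution (ELU), BatchNorm, a per-window WindowNorm, mix pooling
   (a convex combination of max and average pooling) and dropout,
   yielding a feature map ``X_cnn in R^(k x H x L)``.
2. **CTAT block** — ``X_cnn`` is flattened to ``X_flat in R^((k·H) x L)``,
   a learnable positional encoding is added, and two parallel multi-head
   attention paths run: a channel path attending across the k·H channel
   tokens and a time path attending across the L time steps.  The
   attended outputs are fused by a learnable sigmoid gate (one gate
   scalar per head, computed from pooled peakedness summaries of both
   attention maps) and combined with the input through a residual
   connection and layer normalization.
3. **Task head** — softmax classification, linear regression of EMG
   window features, or an autoregressive cross-attention decoder that
   generates EMG feature sequences step by step.

Ablation variants: M1 = base transformer (no conv front end, time
attention only), M2 = + SW-CNN, M3 = + channel-time attention, M4 = full
model.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .nn import (Adam, BatchNorm, Conv1d, Dense, Dropout, LayerNorm, Module,
                 ModuleList, WindowNorm, max_norm_constraint, softmax)

__all__ = [
    "ModelConfig", "AttentionState", "SWCTNet",
    "sliding_window_partition", "mix_pool", "build_variant",
    "save_checkpoint", "load_checkpoint", "ABLATION_VARIANTS",
]

ABLATION_VARIANTS = ("M1", "M2", "M3", "M4")


@dataclass
class ModelConfig:
    """Architecture and training-relevant hyperparameters.

    Key-dimension defaults follow the architecture's stated proportions:
    the channel-attention key dimension is one quarter of the number of
    input channels (rounded up) and the time-attention key dimension is
    ``alpha_t`` times the pooled window length.
    """

    n_channels: int = 9          # input sensor channels (IMU triads)
    seq_len: int = 40            # N_L: input time steps (200 ms at 200 Hz)
    window_len: int = 16         # L_win: model-internal sliding window
    window_step: int = 8         # S
    conv_filters: int = 16       # H
    conv_kernel: int = 5
    use_swcnn: bool = True
    use_channel_attention: bool = True
    n_heads: int = 2
    n_ctat_layers: int = 2
    d_c: int | None = None       # channel-attention key dim (ceil(N_ch/4))
    d_t: int | None = None       # time-attention key dim (ceil(alpha_t * L))
    alpha_t: float = 0.25
    dropout_feature: float = 0.5
    dropout_head: float = 0.5
    dropout_generation: float = 0.7
    spatial_dropout: bool = False
    max_norm: float = 0.25
    mixpool_ratio: float = 0.5
    pool_kernel: int = 2
    pool_stride: int = 2
    task: str = "classification"
    n_classes: int = 3
    n_targets: int = 30          # EMG channels x 6 features
    gen_dim: int = 5             # feature dimension per generated step
    seed: int = 0

    # ------------------------------------------------------------ derived
    @property
    def n_windows(self) -> int:
        return (self.seq_len - self.window_len) // self.window_step + 1

    @property
    def pooled_len(self) -> int:
        return self.window_len // self.pool_stride

    @property
    def feature_channels(self) -> int:
        return self.conv_filters if self.use_swcnn else self.n_channels

    @property
    def n_tokens(self) -> int:
        """k * H — rows of the flattened feature map."""
        return self.n_windows * self.feature_channels

    @property
    def key_dim_channel(self) -> int:
        return self.d_c if self.d_c is not None else math.ceil(self.n_channels / 4)

    @property
    def key_dim_time(self) -> int:
        return self.d_t if self.d_t is not None else max(
            1, math.ceil(self.alpha_t * self.pooled_len))

    def validate(self) -> "ModelConfig":
        if self.seq_len < self.window_len:
            raise ValueError("seq_len must be at least window_len")
        if self.conv_kernel > self.window_len:
            raise ValueError("conv kernel longer than the sliding window")
        if self.pool_kernel != self.pool_stride:
            raise ValueError("mix pooling supports kernel == stride")
        if self.window_len % self.pool_stride != 0:
            raise ValueError("window_len must be divisible by pool_stride")
        if not 0.0 <= self.mixpool_ratio <= 1.0:
            raise ValueError("mixpool_ratio must lie in [0, 1]")
        for p in (self.dropout_feature, self.dropout_head, self.dropout_generation):
            if not 0.0 <= p < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")
        if self.pooled_len % self.n_heads != 0:
            raise ValueError(
                f"n_heads={self.n_heads} must divide the pooled window "
                f"length {self.pooled_len} (channel-path value dim)")
        if self.n_tokens % self.n_heads != 0:
            raise ValueError(
                f"n_heads={self.n_heads} must divide the token count "
                f"{self.n_tokens} (time-path value dim)")
        if self.task not in ("classification", "regression", "generation"):
            raise ValueError(f"unknown task {self.task!r}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known}).validate()


@dataclass
class AttentionState:
    """Attention maps and gate values captured during one forward pass."""

    A_c: list            # per layer: list of (B, kH, kH) arrays per head
    A_t: list            # per layer: list of (B, L, L) arrays per head
    lambda_gate: list    # per layer: (n_heads,) gate values in (0, 1)


def sliding_window_partition(X, window_len: int, step: int):
    """Partition a (..., N_ch, N_L) array into overlapping windows.

    Returns windows stacked on a new axis before the channel axis:
    shape ``(..., L_num, N_ch, L_win)`` with
    ``L_num = floor((N_L - L_win)/S) + 1``; window i holds columns
    ``[i*S, i*S + L_win)``.
    """
    if isinstance(X, Tensor):
        n = X.shape[-1]
        if n < window_len:
            raise ValueError(f"sequence length {n} shorter than window {window_len}")
        k = (n - window_len) // step + 1
        parts = []
        for i in range(k):
            w = X[..., i * step:i * step + window_len]
            parts.append(w.reshape(*w.shape[:-2], 1, *w.shape[-2:]))
        return concat(parts, axis=-3)
    X = np.asarray(X, dtype=float)
    n = X.shape[-1]
    if n < window_len:
        raise ValueError(f"sequence length {n} shorter than window {window_len}")
    k = (n - window_len) // step + 1
    return np.stack([X[..., i * step:i * step + window_len] for i in range(k)],
                    axis=-3)


def mix_pool(x, ratio: float, kernel: int = 2, stride: int = 2):
    """Convex combination of max and average pooling along the last axis.

    ``pooled = ratio * maxpool(x) + (1 - ratio) * avgpool(x)``.  Only
    non-overlapping pooling (kernel == stride) is supported; the trailing
    remainder is dropped.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("mix pooling ratio must lie in [0, 1]")
    if kernel != stride:
        raise ValueError("mix pooling supports kernel == stride only")
    n = x.shape[-1]
    if kernel > n:
        raise ValueError(f"pool kernel {kernel} exceeds signal length {n}")
    m = (n // kernel) * kernel
    if isinstance(x, Tensor):
        xt = x[..., :m].reshape(*x.shape[:-1], m // kernel, kernel)
        return ratio * xt.max(axis=-1) + (1.0 - ratio) * xt.mean(axis=-1)
    x = np.asarray(x, dtype=float)[..., :m]
    xt = x.reshape(*x.shape[:-1], m // kernel, kernel)
    return ratio * xt.max(axis=-1) + (1.0 - ratio) * xt.mean(axis=-1)


class AxisAttention(Module):
    """Multi-head scaled dot-product attention along one token axis.

    Input ``(B, T, D)``: T tokens of dimension D.  Queries and keys are
    projected to ``d_key`` per head; values to ``D / n_heads`` so the
    concatenated head outputs recover dimension D, followed by an output
    projection.
    """

    def __init__(self, token_dim: int, d_key: int, n_heads: int,
                 rng: np.random.Generator):
        super().__init__()
        if token_dim % n_heads != 0:
            raise ValueError("n_heads must divide the token dimension")
        self.n_heads = n_heads
        self.d_key = d_key
        d_v = token_dim // n_heads
        scale = 1.0 / np.sqrt(token_dim)
        for h in range(n_heads):
            setattr(self, f"Wq{h}", Tensor(rng.normal(0, scale, (token_dim, d_key)),
                                           requires_grad=True))
            setattr(self, f"Wk{h}", Tensor(rng.normal(0, scale, (token_dim, d_key)),
                                           requires_grad=True))
            setattr(self, f"Wv{h}", Tensor(rng.normal(0, scale, (token_dim, d_v)),
                                           requires_grad=True))
        self.Wo = Tensor(rng.normal(0, scale, (token_dim, token_dim)),
                         requires_grad=True)

    def __call__(self, x: Tensor):
        """Return (attended output, per-head attention maps, summaries).

        The summary per head is the batch mean of each attention row's
        maximum — a peakedness statistic in (1/T, 1] that feeds the
        fusion gate.
        """
        outs, maps, summaries = [], [], []
        inv_sqrt = 1.0 / np.sqrt(self.d_key)
        for h in range(self.n_heads):
            q = (x @ getattr(self, f"Wq{h}")) * inv_sqrt
            k = x @ getattr(self, f"Wk{h}")
            v = x @ getattr(self, f"Wv{h}")
            A = softmax(q @ k.transpose(0, 2, 1), axis=-1)    # (B, T, T)
            outs.append(A @ v)
            maps.append(A)
            # pooled peakedness statistic, treated as non-differentiated
            summaries.append(A.data.max(axis=-1).mean())
        out = concat(outs, axis=-1) @ self.Wo
        return out, maps, Tensor(np.asarray(summaries))


class CTATLayer(Module):
    """One channel-time attention layer with gated fusion and residual."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.use_channel = cfg.use_channel_attention
        self.time_attn = AxisAttention(cfg.n_tokens, cfg.key_dim_time,
                                       cfg.n_heads, rng)
        if self.use_channel:
            self.chan_attn = AxisAttention(cfg.pooled_len, cfg.key_dim_channel,
                                           cfg.n_heads, rng)
            self.W_g = Tensor(np.zeros((cfg.n_heads, 2)), requires_grad=True)
            self.b_g = Tensor(np.zeros(cfg.n_heads), requires_grad=True)
        self.norm = LayerNorm(cfg.pooled_len)

    def __call__(self, x: Tensor):
        # x: (B, kH, L).  Time path: tokens are the L time steps.
        xt = x.transpose(0, 2, 1)
        out_t, maps_t, s_t = self.time_attn(xt)
        out_t = out_t.transpose(0, 2, 1)
        if self.use_channel:
            out_c, maps_c, s_c = self.chan_attn(x)
            gate_logits = (self.W_g[:, 0] * s_c + self.W_g[:, 1] * s_t
                           + self.b_g)
            lam = gate_logits.sigmoid()                   # (n_heads,)
            lam_bar = lam.mean()
            attn = lam_bar * out_c + (1.0 - lam_bar) * out_t
        else:
            maps_c, lam = [], None
            attn = out_t
        fused = self.norm(attn + x)
        return fused, (maps_c, maps_t, lam)


class SWCTNet(Module):
    """Sliding-window CNN + channel-time attention transformer network."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config.validate()
        rng = np.random.default_rng(config.seed)
        cfg = config
        if cfg.use_swcnn:
            self.conv = Conv1d(cfg.n_channels, cfg.conv_filters,
                               cfg.conv_kernel, rng)
            self.batch_norm = BatchNorm(cfg.conv_filters)
            self.window_norm = WindowNorm(cfg.conv_filters)
        self.drop_feature = Dropout(cfg.dropout_feature,
                                    spatial=cfg.spatial_dropout)
        self.pos_encoding = Tensor(
            rng.normal(0.0, 0.02, (cfg.n_tokens, cfg.pooled_len)),
            requires_grad=True)
        self.ctat_layers = ModuleList(
            [CTATLayer(cfg, rng) for _ in range(cfg.n_ctat_layers)])

        if cfg.task == "classification":
            self.head = Dense(cfg.n_tokens, cfg.n_classes, rng)
            self.drop_head = Dropout(cfg.dropout_head)
        elif cfg.task == "regression":
            self.head = Dense(cfg.n_tokens, cfg.n_targets, rng)
            self.drop_head = Dropout(cfg.dropout_head)
        else:  # generation
            d = cfg.n_tokens
            self.embed_prev = Dense(cfg.gen_dim, d, rng)
            self.Wq_dec = Tensor(rng.normal(0, 1 / np.sqrt(d), (d, d)),
                                 requires_grad=True)
            self.Wk_dec = Tensor(rng.normal(0, 1 / np.sqrt(d), (d, d)),
                                 requires_grad=True)
            self.dec_hidden = Dense(2 * d, d, rng)
            self.dec_out = Dense(d, cfg.gen_dim, rng)
            self.y_start = Tensor(np.zeros(cfg.gen_dim), requires_grad=True)
            self.drop_head = Dropout(cfg.dropout_generation)
        self.reset_rng()

    # ------------------------------------------------------------ plumbing
    def reset_rng(self, seed: int | None = None) -> None:
        """Reset the dropout stream (training determinism under a seed)."""
        base = self.config.seed if seed is None else seed
        self._rng = np.random.default_rng(base + 1)

    def constrained_parameters(self) -> list[Tensor]:
        """Head-layer weights subject to the max-norm constraint."""
        cfg = self.config
        if cfg.task in ("classification", "regression"):
            return [self.head.W]
        return [self.dec_hidden.W, self.dec_out.W]

    # ------------------------------------------------------------- encoder
    def swcnn_forward(self, x: Tensor) -> Tensor:
        """Sliding-window partition + convolutional feature extraction.

        ``x``: (B, N_ch, N_L) -> feature map X_cnn (B, k, H, L_pooled).
        Without the SW-CNN flag the partitioned windows are only
        mix-pooled (base-transformer ablations).
        """
        cfg = self.config
        windows = sliding_window_partition(x, cfg.window_len, cfg.window_step)
        B, k = windows.shape[0], windows.shape[1]
        flat = windows.reshape(B * k, cfg.n_channels, cfg.window_len)
        if cfg.use_swcnn:
            h = self.conv(flat).elu()
            h = self.batch_norm(h)
            h = self.window_norm(h)
        else:
            h = flat
        h = mix_pool(h, cfg.mixpool_ratio, cfg.pool_kernel, cfg.pool_stride)
        h = self.drop_feature(h, self._rng)
        return h.reshape(B, k, cfg.feature_channels, cfg.pooled_len)

    def ctat_forward(self, x_cnn: Tensor, collect_state: bool = False):
        """Flatten, add positional encoding, run the CTAT layers.

        Returns ``X_fused`` of shape (B, k*H, L_pooled) — the same shape
        as the flattened input (residual contract) — and optionally the
        attention state.
        """
        cfg = self.config
        B = x_cnn.shape[0]
        x = x_cnn.reshape(B, cfg.n_tokens, cfg.pooled_len)
        x = x + self.pos_encoding
        state = AttentionState([], [], []) if collect_state else None
        for layer in self.ctat_layers:
            x, (maps_c, maps_t, lam) = layer(x)
            if collect_state:
                state.A_c.append([m.data for m in maps_c])
                state.A_t.append([m.data for m in maps_t])
                state.lambda_gate.append(
                    lam.data.copy() if lam is not None else None)
        return (x, state) if collect_state else x

    def encode(self, x, collect_state: bool = False):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        return self.ctat_forward(self.swcnn_forward(x), collect_state)

    # --------------------------------------------------------------- heads
    def _pool_tokens(self, x_fused: Tensor) -> Tensor:
        # mean over the time axis -> one (k*H)-dim vector per sample
        return x_fused.mean(axis=2)

    def classification_head(self, x_fused: Tensor) -> Tensor:
        pooled = self.drop_head(self._pool_tokens(x_fused), self._rng)
        return softmax(self.head(pooled), axis=-1)

    def classification_logits(self, x_fused: Tensor) -> Tensor:
        pooled = self.drop_head(self._pool_tokens(x_fused), self._rng)
        return self.head(pooled)

    def regression_head(self, x_fused: Tensor) -> Tensor:
        pooled = self.drop_head(self._pool_tokens(x_fused), self._rng)
        return self.head(pooled)

    def decoder_step(self, y_prev: Tensor, memory: Tensor) -> Tensor:
        """One autoregressive step: cross-attend to the encoder memory.

        ``y_prev``: (B, gen_dim); ``memory``: (B, kH, L) fused features.
        The previous output is embedded as the query, attends over the
        memory's time tokens, and a two-layer head maps [context; query]
        to the next feature vector.
        """
        B = memory.shape[0]
        tokens = memory.transpose(0, 2, 1)            # (B, L, kH)
        q = self.embed_prev(y_prev)                   # (B, kH)
        scale = 1.0 / np.sqrt(self.Wq_dec.shape[1])
        qp = (q @ self.Wq_dec).reshape(B, -1, 1)      # (B, kH, 1)
        kp = tokens @ self.Wk_dec                     # (B, L, kH)
        scores = (kp @ qp).reshape(B, -1) * scale     # (B, L)
        a = softmax(scores, axis=-1).reshape(B, 1, -1)
        context = (a @ tokens).reshape(B, -1)         # (B, kH)
        h = self.dec_hidden(concat([context, q], axis=-1)).tanh()
        h = self.drop_head(h, self._rng)
        return self.dec_out(h)

    def generation_decoder(self, memory, horizon: int,
                           y_prefix: np.ndarray | None = None,
                           teacher: np.ndarray | None = None) -> Tensor:
        """Autoregressively generate ``horizon`` feature vectors.

        ``memory`` is either a single fused feature map (B, kH, L) used
        at every step, or a per-step sequence (B, T, kH, L).  With
        ``teacher`` (B, T, gen_dim) given and the module in training
        mode, ground-truth previous outputs are fed back (teacher
        forcing); otherwise the decoder free-runs from its own outputs.
        ``y_prefix`` seeds the first previous-output; a learned start
        token is used when absent.
        """
        if horizon < 1:
            raise ValueError("generation horizon must be >= 1")
        per_step = isinstance(memory, Tensor) and memory.ndim == 4
        B = memory.shape[0]
        if y_prefix is not None:
            y_prev = Tensor(np.asarray(y_prefix, dtype=float))
        else:
            y_prev = self.y_start.reshape(1, -1) * Tensor(np.ones((B, 1)))
        outs = []
        for t in range(horizon):
            mem_t = memory[:, t] if per_step else memory
            y_t = self.decoder_step(y_prev, mem_t)
            outs.append(y_t.reshape(B, 1, -1))
            if teacher is not None and self.training:
                y_prev = Tensor(np.asarray(teacher[:, t], dtype=float))
            else:
                y_prev = y_t
        return concat(outs, axis=1)                   # (B, horizon, gen_dim)

    # -------------------------------------------------------------- forward
    def forward(self, x, collect_state: bool = False, **gen_kwargs):
        """Task-dispatching forward pass on a (B, N_ch, N_L) batch."""
        if collect_state:
            fused, state = self.encode(x, collect_state=True)
        else:
            fused = self.encode(x)
            state = None
        cfg = self.config
        if cfg.task == "classification":
            out = self.classification_head(fused)
        elif cfg.task == "regression":
            out = self.regression_head(fused)
        else:
            out = self.generation_decoder(fused,
                                          gen_kwargs.pop("horizon", 1),
                                          **gen_kwargs)
        return (out, state) if collect_state else out

    __call__ = forward


def build_variant(base: ModelConfig, variant: str) -> SWCTNet:
    """Construct an ablation variant M1..M4 from a base configuration."""
    flags = {
        "M1": dict(use_swcnn=False, use_channel_attention=False),
        "M2": dict(use_swcnn=True, use_channel_attention=False),
        "M3": dict(use_swcnn=False, use_channel_attention=True),
        "M4": dict(use_swcnn=True, use_channel_attention=True),
    }
    if variant not in flags:
        raise ValueError(f"unknown ablation variant {variant!r}")
    cfg = dataclasses.replace(base, **flags[variant])
    return SWCTNet(cfg)


def save_checkpoint(model: SWCTNet, path: str | Path) -> None:
    """Write parameters (.npz) with a JSON config side-car."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.config.to_dict(), indent=2))


def load_checkpoint(path: str | Path) -> SWCTNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    cfg = ModelConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
    model = SWCTNet(cfg)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
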