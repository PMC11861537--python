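"""Neural-network building blocks on the numpy autodiff engine.

Layers hold named :class:`~swctnet.autodiff.Tensor` parameters and are
pure functions of (input, parameters, training flag, rng).  Randomness
(initialization, dropout masks) is funnelled through explicit
``numpy.random.Generator`` objects so every forward pass is reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d

__all__ = [
    "Module", "ModuleList", "Dense", "Conv1d", "BatchNorm", "WindowNorm", "LayerNorm",
    "Dropout", "softmax", "log_softmax", "Adam", "max_norm_constraint",
]


class Module:
    """Base class: parameter registry and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and getattr(value, "requires_grad", False):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> dict[str, Tensor]:
        out = dict(self._params)
        for cname, child in self._children.items():
            for pname, p in child.parameters().items():
                out[f"{cname}.{pname}"] = p
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self._params.items()}
        if hasattr(self, "_buffers"):
            state.update({k: v.copy() for k, v in self._buffers().items()})
        for cname, child in self._children.items():
            for k, v in child.state_dict().items():
                state[f"{cname}.{k}"] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self._set_state(k, np.array(v, dtype=np.float64))

    def _set_state(self, key: str, value: np.ndarray) -> None:
        head, _, rest = key.partition(".")
        if rest and head in self._children:
            self._children[head]._set_state(rest, value)
        elif head in self._params:
            self._params[head].data = value
        else:
            object.__setattr__(self, head, value)


class ModuleList(Module):
    """Sequence of child modules registered by index."""

    def __init__(self, modules=()):
        super().__init__()
        self._items: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        setattr(self, f"m{len(self._items)}", module)
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


def _param(rng: np.random.Generator, shape, scale: float | None = None) -> Tensor:
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        if len(shape) == 3:                       # conv (H, C, K)
            fan_in = shape[1] * shape[2]
        scale = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Dense(Module):
    """Affine map on the last axis: y = x @ W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _param(rng, (d_in, d_out))
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1d(Module):
    """Same-padded 1-D convolution over the last (time) axis."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.W = _param(rng, (c_out, c_in, kernel))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b)


class BatchNorm(Module):
    """Normalize each feature channel over the batch (and time) axes.

    Input shape (B, C, L).  Running statistics are tracked for eval mode.
    """

    def __init__(self, n_channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True).mean(axis=2, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True).mean(axis=2, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class WindowNorm(Module):
    """Per-window normalization along the time-within-window axis.

    Each (window, channel) slice is standardized along time with a
    variance floor (sigma >= ``sigma_floor``), then scaled and shifted by
    learnable per-channel parameters — a normalization scoped to the
    sliding window rather than the batch, which suppresses local
    non-stationarity.
    """

    def __init__(self, n_channels: int, sigma_floor: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.sigma_floor = sigma_floor

    def __call__(self, x: Tensor) -> Tensor:
        # x: (..., C, L); normalize along the last axis per channel slice
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        sigma = (var + self.sigma_floor ** 2) ** 0.5
        xhat = (x - mu) / sigma
        return xhat * self.gamma.reshape(-1, 1) + self.beta.reshape(-1, 1)


class LayerNorm(Module):
    """Standardize the last axis of each token, with learnable affine."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode.

    With ``spatial=True`` whole channels (axis 1) are dropped together,
    which suits strongly spatially-correlated multichannel signals.
    """

    def __init__(self, p: float, spatial: bool = False):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.spatial = spatial

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        if self.spatial and x.ndim >= 3:
            shape = (x.shape[0], x.shape[1]) + (1,) * (x.ndim - 2)
        else:
            shape = x.shape
        mask = (rng.random(shape) < keep).astype(float) / keep
        return x * Tensor(mask)


from .autodiff import log_softmax, softmax  # fused, numerically stable


def max_norm_constraint(params: list[Tensor], max_norm: float = 0.25) -> None:
    """Project each weight's rows onto the ball of radius ``max_norm``.

    Applied after every optimizer step to the constrained (head) layers;
    norms are computed along the last axis for matrices.
    """
    for p in params:
        w = p.data
        if w.ndim == 1:
            norm = np.linalg.norm(w)
            if norm > max_norm:
                p.data = w * (max_norm / norm)
        else:
            norms = np.linalg.norm(w, axis=-1, keepdims=True)
            factor = np.minimum(1.0, max_norm / np.maximum(norms, 1e-30))
            p.data = w * factor


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
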