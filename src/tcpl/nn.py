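"""Neural-network building blocks on top of :mod:`tcpl.autograd`.

Layers follow the usual conventions: a :class:`Module` owns named parameters,
``train()``/``eval()`` toggles dropout, and all randomness (initialisation and
dropout masks) flows through explicitly passed ``numpy.random.Generator``
objects so that runs are reproducible bit for bit.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "CausalConv1d",
    "LayerNorm",
    "Dropout",
    "softmax",
    "cross_entropy",
    "avg_pool1d",
    "xavier_uniform",
]


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int | None = None, fan_out: int | None = None,
                   gain: float = 1.0) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    if fan_in is None:
        fan_in = int(np.prod(shape[1:]))
    if fan_out is None:
        fan_out = shape[0]
    bound = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, mod in self._modules.items():
            out.update(mod.named_parameters(prefix + name + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def modules(self) -> list["Module"]:
        out = [self]
        for m in self._modules.values():
            out.extend(m.modules())
        return out

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(
            xavier_uniform(rng, (in_features, out_features), fan_in=in_features,
                           fan_out=out_features),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class CausalConv1d(Module):
    """Causal dilated 1-D convolution over the last (time) axis.

    Input ``(..., C_in, T)`` -> output ``(..., C_out, T)`` with
    ``y[c, t] = sum_{c', j} W[c, c', j] x[c', t - j*dilation] + b[c]``,
    zero-padded on the left so the output at time t depends only on inputs
    at times <= t.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.weight = Tensor(
            xavier_uniform(rng, (out_channels, in_channels, kernel_size),
                           fan_in=in_channels * kernel_size, fan_out=out_channels),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-2] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[-2]}")
        T = x.shape[-1]
        y = None
        for j in range(self.kernel_size):
            shift = j * self.dilation
            xj = x if shift == 0 else x.pad_last(shift)[..., :T]
            # (C_out, C_in) @ (..., C_in, T) -> (..., C_out, T)
            term = self.weight[:, :, j] @ xj
            y = term if y is None else y + term
        if self.bias is not None:
            y = y + self.bias.reshape(self.out_channels, 1)
        return y


class LayerNorm(Module):
    """Layer normalisation over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc / (var + self.eps).sqrt()
        return y * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask drawn from the given rng."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training mode without an rng bound")
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtracting the detached max is gradient-exact for softmax
    m = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row-wise softmax of ``logits``."""
    labels = np.asarray(labels)
    n, k = logits.shape
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} does not match logits rows {n}")
    m = Tensor(np.max(logits.data, axis=1, keepdims=True))
    lse = (logits - m).exp().sum(axis=1).log() + m.reshape(n)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    picked = (logits * Tensor(onehot)).sum(axis=1)
    return (lse - picked).mean()


def avg_pool1d(x: Tensor, stride: int) -> Tensor:
    """Non-overlapping temporal average pooling on the last axis.

    Truncates on the right if T is not divisible by the stride.
    """
    if stride == 1:
        return x
    T = x.shape[-1]
    T2 = (T // stride) * stride
    if T2 != T:
        x = x[..., :T2]
    return x.reshape(*x.shape[:-1], T2 // stride, stride).mean(axis=-1)
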