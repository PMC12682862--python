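"""Task-conditioned prompt (TCP) path: support encoder and prompt generator.

A support set of a few labelled trials from one subject is encoded trial by
trial (two temporal convolutions, global average over time, linear projection
to d), mean-pooled into a subject summary h_s, and mapped by a two-layer MLP
to k prompt tokens of dimension d. Prompts are deterministic functions of the
support set and the parameters (phi = encoder, psi = generator); they are not
free parameters and receive gradient only through phi and psi.

Class labels of the support trials are carried for episode bookkeeping but are
not consumed by the prompt path, which summarises the subject's signal
statistics rather than class identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor

__all__ = ["SupportSet", "SupportEncoder", "PromptGenerator", "TCPModule"]

PROMPT_INIT_STD = 0.01  # target std of prompt entries at initialisation


@dataclass
class SupportSet:
    """Balanced few-shot calibration set from a single subject."""

    X: np.ndarray          # n_support x C x T
    y: np.ndarray          # class indices
    subject_id: str
    n_shot: int

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 3 or len(self.y) != self.X.shape[0]:
            raise ValueError("support set must be n x C x T with matching labels")
        _, counts = np.unique(self.y, return_counts=True)
        if not (counts == self.n_shot).all():
            raise ValueError(
                f"support set must be balanced with {self.n_shot} trials per class; "
                f"got counts {counts.tolist()}")


class SupportEncoder(nn.Module):
    """f_phi: one trial (C x T) -> d-vector embedding."""

    def __init__(self, n_channels: int, d: int, rng: np.random.Generator,
                 kernel: int = 3):
        super().__init__()
        self.n_channels = n_channels
        self.conv1 = nn.CausalConv1d(n_channels, d, kernel, 1, rng)
        self.conv2 = nn.CausalConv1d(d, d, kernel, 1, rng)
        self.proj = nn.Linear(d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, C, T) -> (N, d)."""
        if x.shape[-2] != self.n_channels:
            raise ValueError(
                f"support encoder built for {self.n_channels} channels, "
                f"got {x.shape[-2]}")
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        pooled = h.mean(axis=-1)  # global average over time
        return self.proj(pooled)


def pool_support(embeddings: Tensor) -> Tensor:
    """Mean pooling over support embeddings: (N, d) -> (d,).

    Rows are summed in a canonical (lexicographically sorted) order so the
    pooled mean is bitwise invariant to any permutation of the support set,
    not merely invariant up to floating-point rounding.
    """
    if embeddings.shape[0] == 0:
        raise ValueError("cannot pool an empty support set")
    order = np.lexsort(embeddings.data.T[::-1])  # canonical row order
    return embeddings[order].mean(axis=0)


class PromptGenerator(nn.Module):
    """g_psi: subject summary h_s (d,) -> prompt tokens (k, d).

    Two-layer MLP (hidden width d, ReLU). The output layer is initialised
    with small Gaussian weights and zero bias so that initial prompt entries
    have std ~= 0.01, reconciling a small-prompt initialisation with prompts
    being deterministic outputs rather than free parameters.
    """

    def __init__(self, k: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.k, self.d = k, d
        self.hidden = nn.Linear(d, d, rng)
        self.out = nn.Linear(d, k * d, rng)
        # overwrite Xavier: small-output initialisation for the prompt layer
        self.out.weight.data = rng.normal(0.0, PROMPT_INIT_STD / np.sqrt(d),
                                          size=(d, k * d))
        self.out.bias.data = np.zeros(k * d)

    def __call__(self, h_s: Tensor) -> Tensor:
        return self.out(self.hidden(h_s).relu()).reshape(self.k, self.d)


class TCPModule(nn.Module):
    """Full prompt path: support set -> k x d PromptSet."""

    def __init__(self, n_channels: int, k: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.encoder = SupportEncoder(n_channels, d, rng)
        self.generator = PromptGenerator(k, d, rng)

    def __call__(self, support_x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(support_x, Tensor):
            support_x = Tensor(support_x)
        e = self.encoder(support_x)      # (N, d)
        h_s = pool_support(e)            # (d,)
        return self.generator(h_s)       # (k, d)
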