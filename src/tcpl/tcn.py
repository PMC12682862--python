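"""Residual causal dilated temporal convolutional network (TCN) backbone.

Maps a preprocessed trial (C x T) to a temporal token sequence (T' x d). Four
residual blocks, each with two causal dilated convolutions (kernel 3,
dilations 1/2/4/8 across blocks, widths 64/64/128/128 by default), ReLU and
dropout; the residual path uses a 1x1 convolution when channel counts change.
Temporal average pooling (stride 2 after blocks 2 and 4 by default) shortens
the sequence to T' = T/4 before a linear projection to the model dimension d,
keeping the downstream attention cost manageable.

With kernel 3 the stack's receptive field is 1 + sum over blocks of
2*(k-1)*dilation = 61 samples under the default dilations.
"""

from __future__ import annotations

import logging

import numpy as np

from . import nn
from .autograd import Tensor
from .config import ModelConfig

__all__ = ["TCNBlock", "TCN", "receptive_field"]

log = logging.getLogger(__name__)


def receptive_field(kernel: int, dilations: tuple[int, ...]) -> int:
    """Receptive field of the stacked blocks (two convs per block)."""
    return 1 + sum(2 * (kernel - 1) * d for d in dilations)


class TCNBlock(nn.Module):
    """conv -> ReLU -> dropout -> conv -> ReLU -> dropout, plus residual."""

    def __init__(self, in_channels: int, width: int, kernel: int, dilation: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.CausalConv1d(in_channels, width, kernel, dilation, rng)
        self.conv2 = nn.CausalConv1d(width, width, kernel, dilation, rng)
        self.drop1 = nn.Dropout(dropout)
        self.drop2 = nn.Dropout(dropout)
        self.residual = (nn.CausalConv1d(in_channels, width, 1, 1, rng)
                         if in_channels != width else None)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.drop1(self.conv1(x).relu())
        h = self.drop2(self.conv2(h).relu())
        res = x if self.residual is None else self.residual(x)
        return h + res


class TCN(nn.Module):
    """Stacked TCN blocks with optional temporal pooling and output projection."""

    def __init__(self, n_channels: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.n_channels = n_channels
        self.cfg = cfg
        self.blocks: list[TCNBlock] = []
        in_ch = n_channels
        for i, (dil, width) in enumerate(zip(cfg.tcn_dilations, cfg.tcn_widths)):
            block = TCNBlock(in_ch, width, cfg.tcn_kernel, dil, cfg.tcn_dropout, rng)
            setattr(self, f"block{i}", block)
            self.blocks.append(block)
            in_ch = width
        # average pooling applied after every second block (blocks 2 and 4)
        self.pool_after = tuple(i for i in range(len(self.blocks)) if i % 2 == 1)
        self.proj = (nn.Linear(in_ch, cfg.d, rng) if in_ch != cfg.d else None)

    @property
    def total_pool(self) -> int:
        return self.cfg.pool_stride ** len(self.pool_after)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, C, T) -> feature sequence (B, T', d)."""
        if x.shape[-2] != self.n_channels:
            raise ValueError(
                f"TCN built for {self.n_channels} input channels, got {x.shape[-2]}")
        T = x.shape[-1]
        if self.cfg.pool_stride > 1 and T % self.total_pool != 0:
            log.warning("T=%d not divisible by pooling factor %d; right-truncating",
                        T, self.total_pool)
        h = x
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i in self.pool_after and self.cfg.pool_stride > 1:
                h = nn.avg_pool1d(h, self.cfg.pool_stride)
        tokens = h.swapaxes(-1, -2)  # (B, T', width)
        if self.proj is not None:
            tokens = self.proj(tokens)
        return tokens
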