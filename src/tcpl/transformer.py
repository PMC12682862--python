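"""Prompt-prefixed Transformer encoder and classification head.

Prompt tokens join the TCN feature sequence as prefix rows of the input
Z = [P_s; H]; attention is full (unmasked), so sequence tokens attend to
prompt-derived keys and values and thereby receive subject-conditioned
modulation. Layers are post-norm (LayerNorm after MHSA and after FFN), with
learned absolute positional embeddings added to the sequence tokens only —
prompts are position-free context.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autograd import Tensor, concatenate
from .config import ModelConfig

__all__ = [
    "prepend_prompts",
    "MultiHeadAttention",
    "TransformerLayer",
    "PromptTransformer",
    "ClassifierHead",
]


def prepend_prompts(prompts: Tensor | None, features: Tensor) -> tuple[Tensor, int]:
    """Concatenate prompts (k, d) as prefix rows of features (B, T', d).

    Returns the token sequence (B, k+T', d) and the prefix length. ``prompts``
    of None (or k=0) returns the features unchanged — the prompt-free ablation.
    Prompts are injected only here, never into raw EEG channels.
    """
    if prompts is None or prompts.shape[0] == 0:
        return features, 0
    if prompts.shape[-1] != features.shape[-1]:
        raise ValueError(
            f"prompt dim {prompts.shape[-1]} != feature dim {features.shape[-1]}")
    B = features.shape[0]
    k, d = prompts.shape
    ones = Tensor(np.ones((B, 1, 1)))
    tiled = prompts.reshape(1, k, d) * ones  # broadcast prompts over the batch
    return concatenate([tiled, features], axis=1), k


class MultiHeadAttention(nn.Module):
    """Standard multi-head scaled dot-product self-attention (full, unmasked)."""

    def __init__(self, d: int, heads: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        if d % heads != 0:
            raise ValueError("model dim must be divisible by head count")
        self.heads = heads
        self.d_head = d // heads
        self.wq = nn.Linear(d, d, rng)
        self.wk = nn.Linear(d, d, rng)
        self.wv = nn.Linear(d, d, rng)
        self.wo = nn.Linear(d, d, rng)
        self.attn_drop = nn.Dropout(dropout)

    def attention_weights(self, z: Tensor) -> np.ndarray:
        """Post-softmax attention weights (B, h, N, N) — diagnostic only."""
        q, k, _ = self._project(z)
        scores = q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(self.d_head))
        return nn.softmax(scores, axis=-1).data

    def _project(self, z: Tensor):
        B, N, d = z.shape

        def split(x: Tensor) -> Tensor:
            return x.reshape(B, N, self.heads, self.d_head).transpose(0, 2, 1, 3)

        return split(self.wq(z)), split(self.wk(z)), split(self.wv(z))

    def __call__(self, z: Tensor) -> Tensor:
        B, N, d = z.shape
        q, k, v = self._project(z)                      # (B, h, N, d_h)
        scores = q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(self.d_head))
        weights = nn.softmax(scores, axis=-1)           # rows sum to 1
        weights = self.attn_drop(weights)
        out = weights @ v                               # (B, h, N, d_h)
        merged = out.transpose(0, 2, 1, 3).reshape(B, N, d)
        return self.wo(merged)


class TransformerLayer(nn.Module):
    """Post-norm block: LN(z + MHSA(z)) then LN(y + FFN(y))."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.d
        self.mhsa = MultiHeadAttention(d, cfg.heads, cfg.transformer_dropout, rng)
        self.ln1 = nn.LayerNorm(d)
        self.ln2 = nn.LayerNorm(d)
        self.ffn1 = nn.Linear(d, cfg.ffn_dim, rng)
        self.ffn2 = nn.Linear(cfg.ffn_dim, d, rng)
        self.drop = nn.Dropout(cfg.transformer_dropout)

    def __call__(self, z: Tensor) -> Tensor:
        y = self.ln1(z + self.mhsa(z))
        ffn = self.ffn2(self.ffn1(y).relu())
        return self.ln2(y + self.drop(ffn))


class PromptTransformer(nn.Module):
    """Stack of Transformer layers over a prompt-prefixed token sequence."""

    def __init__(self, cfg: ModelConfig, seq_len: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.seq_len = seq_len
        self.layers: list[TransformerLayer] = []
        for i in range(cfg.transformer_layers):
            layer = TransformerLayer(cfg, rng)
            setattr(self, f"layer{i}", layer)
            self.layers.append(layer)
        if cfg.positional == "learned":
            self.pos = Tensor(rng.normal(0.0, 0.02, size=(seq_len, cfg.d)),
                              requires_grad=True)
        else:
            self.pos = None

    def __call__(self, features: Tensor, prompts: Tensor | None) -> tuple[Tensor, int]:
        """features (B, T', d), prompts (k, d) or None -> (B, k+T', d), prefix_len."""
        if self.pos is not None:
            if features.shape[1] != self.seq_len:
                raise ValueError(
                    f"positional table built for T'={self.seq_len}, "
                    f"got {features.shape[1]}")
            features = features + self.pos
        z, prefix = prepend_prompts(prompts, features)
        for layer in self.layers:
            z = layer(z)
        return z, prefix


class ClassifierHead(nn.Module):
    """Mean-pool token rows (sequence-only by default) -> linear logits."""

    def __init__(self, d: int, n_classes: int, rng: np.random.Generator,
                 pooling: str = "sequence"):
        super().__init__()
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        if pooling not in ("sequence", "all"):
            raise ValueError("pooling must be 'sequence' or 'all'")
        self.pooling = pooling
        self.fc = nn.Linear(d, n_classes, rng)

    def __call__(self, z: Tensor, prefix_len: int) -> Tensor:
        if self.pooling == "sequence" and prefix_len > 0:
            z = z[:, prefix_len:, :]
        return self.fc(z.mean(axis=1))
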