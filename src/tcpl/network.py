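"""Full decoding network: prompt path + TCN backbone + prompt-prefixed
Transformer + classification head, with ablation variants and checkpoint I/O.

Variants share one code path, differing only in which components exist:

- ``full``            prompt path, TCN, Transformer, head
- ``no_tcp``          TCN + Transformer, no prompt path (k = 0)
- ``no_transformer``  TCN features mean-pooled straight into the head
- ``no_tcn``          per-sample linear projection of the raw trial to d-dim
                      tokens, then the (prompt-conditioned) Transformer

Parameters are partitioned into three named groups: ``theta`` (backbone +
Transformer + head), ``phi`` (support encoder) and ``psi`` (prompt
generator); checkpoints store the groups separately.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor
from .config import ModelConfig
from .prompt import TCPModule
from .tcn import TCN
from .transformer import ClassifierHead, PromptTransformer

__all__ = ["TCPLNetwork", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = "0.1.0"


class _InputProjection(nn.Module):
    """Per-sample linear map C -> d turning a raw trial into d-dim tokens."""

    def __init__(self, n_channels: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.n_channels = n_channels
        self.proj = nn.Linear(n_channels, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-2] != self.n_channels:
            raise ValueError(
                f"input projection built for {self.n_channels} channels, "
                f"got {x.shape[-2]}")
        return self.proj(x.swapaxes(-1, -2))  # (B, T, d)


class TCPLNetwork(nn.Module):
    """The task-conditioned prompt learning network."""

    def __init__(self, n_channels: int, n_classes: int, n_samples: int,
                 cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.n_samples = n_samples
        self.cfg = cfg

        self.has_tcn = cfg.variant != "no_tcn"
        self.has_transformer = cfg.variant != "no_transformer"
        self.has_tcp = cfg.variant in ("full", "no_tcn") and cfg.k > 0

        if self.has_tcn:
            self.tcn = TCN(n_channels, cfg, rng)
            seq_len = n_samples // self.tcn.total_pool
        else:
            self.input_proj = _InputProjection(n_channels, cfg.d, rng)
            seq_len = n_samples
        self.seq_len = seq_len

        if self.has_transformer:
            self.transformer = PromptTransformer(cfg, seq_len, rng)
        if self.has_tcp:
            self.tcp = TCPModule(n_channels, cfg.k, cfg.d, rng)
        self.head = ClassifierHead(cfg.d, n_classes, rng, cfg.head_pooling)

    # --------------------------------------------------------------- plumbing

    def bind_rng(self, rng: np.random.Generator) -> None:
        """Bind the dropout-mask generator (training-time stochasticity)."""
        for m in self.modules():
            if isinstance(m, nn.Dropout):
                m.rng = rng

    def parameter_groups(self) -> dict[str, dict[str, Tensor]]:
        """Named parameter groups theta / phi / psi."""
        phi, psi = {}, {}
        if self.has_tcp:
            phi = self.tcp.encoder.named_parameters("tcp.encoder.")
            psi = self.tcp.generator.named_parameters("tcp.generator.")
        theta = {k: v for k, v in self.named_parameters().items()
                 if k not in phi and k not in psi}
        return {"theta": theta, "phi": phi, "psi": psi}

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # ---------------------------------------------------------------- forward

    def prompts_from_support(self, support_x: np.ndarray | Tensor) -> Tensor | None:
        """Generate the PromptSet (k x d) from a support set; None without TCP."""
        if not self.has_tcp:
            return None
        return self.tcp(support_x)

    def forward(self, x: np.ndarray | Tensor,
                prompts: Tensor | None = None) -> Tensor:
        """Trials (B, C, T) [+ prompts (k, d)] -> logits (B, n_classes)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        tokens = self.tcn(x) if self.has_tcn else self.input_proj(x)
        if self.has_transformer:
            z, prefix = self.transformer(tokens, prompts if self.has_tcp else None)
        else:
            z, prefix = tokens, 0
        return self.head(z, prefix)

    __call__ = forward

    def predict_proba(self, x: np.ndarray, prompts: Tensor | None = None) -> np.ndarray:
        logits = self.forward(x, prompts).data
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


# -------------------------------------------------------------- checkpoints


def save_checkpoint(network: TCPLNetwork, path: str | Path) -> None:
    """Single-file checkpoint: parameter groups + config echo + version."""
    import dataclasses

    groups = network.parameter_groups()
    arrays = {}
    for gname, params in groups.items():
        for pname, p in params.items():
            arrays[f"{gname}/{pname}"] = p.data
    meta = {
        "version": CHECKPOINT_VERSION,
        "n_channels": network.n_channels,
        "n_classes": network.n_classes,
        "n_samples": network.n_samples,
        "config": dataclasses.asdict(network.cfg),
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> TCPLNetwork:
    """Rebuild a network from a checkpoint; the probe forward is bitwise stable."""
    try:
        with np.load(path) as f:
            arrays = {k: f[k] for k in f.files}
    except Exception as exc:
        raise IOError(f"unreadable or truncated checkpoint {path}: {exc}") from exc
    if "__meta__" not in arrays:
        raise IOError(f"checkpoint {path} has no metadata record")
    meta = json.loads(arrays.pop("__meta__").tobytes().decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint version {meta.get('version')!r} does not match "
            f"package checkpoint version {CHECKPOINT_VERSION!r}")
    cfg = ModelConfig(**meta["config"])
    net = TCPLNetwork(meta["n_channels"], meta["n_classes"], meta["n_samples"],
                      cfg, np.random.default_rng(0))
    state = {}
    for key, arr in arrays.items():
        _, pname = key.split("/", 1)
        state[pname] = arr
    net.load_state_dict(state)
    net.eval()
    return net
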