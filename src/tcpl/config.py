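"""Configuration objects, defaults, and flat key:value config-file loading.

Defaults follow the published training recipe: Adam at lr 1e-3 with cosine
annealing, weight decay 1e-4, 16 episodes per batch, k=10 prompt tokens of
dimension d=64, a 4-block TCN with dilations [1,2,4,8] and widths
[64,64,128,128], a 4-layer / 8-head Transformer with FFN width 256, dropout
0.1 and prompt-norm weight lambda=1e-4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "default_config",
    "load_config",
    "dump_config",
    "config_to_objects",
    "small_model_config",
    "small_train_config",
]

VARIANTS = ("full", "no_tcp", "no_transformer", "no_tcn")


@dataclass
class ModelConfig:
    """Architecture hyperparameters for the prompt-conditioned TCN-Transformer."""

    k: int = 10                  # prompt tokens
    d: int = 64                  # model / prompt dimension
    tcn_kernel: int = 3
    tcn_dilations: tuple[int, ...] = (1, 2, 4, 8)
    tcn_widths: tuple[int, ...] = (64, 64, 128, 128)
    tcn_dropout: float = 0.1
    pool_stride: int = 2         # temporal avg-pool after blocks 2 and 4; 1 = off
    transformer_layers: int = 4
    heads: int = 8
    ffn_dim: int = 256
    transformer_dropout: float = 0.1
    positional: str = "learned"  # learned | none (sequence tokens only)
    head_pooling: str = "sequence"  # sequence | all
    variant: str = "full"

    def __post_init__(self):
        self.tcn_dilations = tuple(int(v) for v in self.tcn_dilations)
        self.tcn_widths = tuple(int(v) for v in self.tcn_widths)
        if self.k < 0:
            raise ValueError("prompt count (k) must be >= 0")
        if self.d < 1:
            raise ValueError("model dimension (d) must be >= 1")
        if len(self.tcn_dilations) != len(self.tcn_widths):
            raise ValueError("tcn_dilations and tcn_widths must have equal length")
        if self.tcn_kernel < 1:
            raise ValueError("tcn_kernel must be >= 1")
        if self.pool_stride < 1:
            raise ValueError("pool_stride must be >= 1")
        if self.d % self.heads != 0:
            raise ValueError("model dimension (d) must be divisible by heads")
        if not 0 <= self.tcn_dropout < 1 or not 0 <= self.transformer_dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.positional not in ("learned", "none"):
            raise ValueError("positional must be 'learned' or 'none'")
        if self.head_pooling not in ("sequence", "all"):
            raise ValueError("head_pooling must be 'sequence' or 'all'")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class TrainConfig:
    """Episodic meta-training hyperparameters."""

    lr: float = 1e-3
    lr_min: float = 0.0          # cosine annealing floor
    weight_decay: float = 1e-4
    batch_episodes: int = 16
    max_epochs: int = 100
    patience: int = 10           # early stopping on validation accuracy
    episodes_per_epoch: int | None = None  # default 10 x n_training_subjects
    n_shot: int = 5
    lam: float = 1e-4            # prompt-norm regularisation weight
    query_cap: int | None = None
    freeze_backbone: bool = False
    validation: str = "rotating"  # rotating held-out subject | fixed

    def __post_init__(self):
        if self.validation not in ("fixed", "rotating"):
            raise ValueError("validation must be 'fixed' or 'rotating'")
        if self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("lr must be positive and weight_decay non-negative")
        if self.batch_episodes < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch_episodes, max_epochs, patience must be >= 1")
        if self.n_shot < 1:
            raise ValueError("n_shot must be >= 1")
        if self.lam < 0:
            raise ValueError("prompt-norm weight (lam) must be >= 0")


_FIELD_OWNERS = {f.name: ModelConfig for f in dataclasses.fields(ModelConfig)}
_FIELD_OWNERS.update({f.name: TrainConfig for f in dataclasses.fields(TrainConfig)})


def default_config() -> dict:
    """The fully resolved default configuration as a flat dict."""
    cfg = {}
    for obj in (ModelConfig(), TrainConfig()):
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            cfg[f.name] = list(v) if isinstance(v, tuple) else v
    return cfg


def load_config(path: str | Path | None) -> dict:
    """Load a flat key:value (YAML) config; absent keys take defaults.

    Unknown keys and invariant violations raise with the offending key named.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must be a flat key: value mapping")
        for key, value in user.items():
            if key not in _FIELD_OWNERS:
                raise KeyError(f"unknown configuration key: {key!r}")
            cfg[key] = value
    config_to_objects(cfg)  # validate
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, default_flow_style=None, sort_keys=True)


def config_to_objects(cfg: dict) -> tuple[ModelConfig, TrainConfig]:
    """Split a flat config dict into validated dataclass instances."""
    model_kwargs, train_kwargs = {}, {}
    for key, value in cfg.items():
        owner = _FIELD_OWNERS.get(key)
        if owner is None:
            raise KeyError(f"unknown configuration key: {key!r}")
        (model_kwargs if owner is ModelConfig else train_kwargs)[key] = value
    return ModelConfig(**model_kwargs), TrainConfig(**train_kwargs)


def small_model_config(**overrides) -> ModelConfig:
    """Desk-scale architecture: same structure, reduced width/depth.

    Used by the bundled benchmark experiments so full meta-training runs on a
    single CPU in minutes; every code path (prompts, TCN, Transformer, head)
    is identical to the default model.
    """
    kwargs = dict(
        k=4, d=32,
        tcn_widths=(16, 16, 32, 32),
        tcn_dilations=(1, 2, 4, 8),
        transformer_layers=2, heads=4, ffn_dim=64)
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def small_train_config(**overrides) -> TrainConfig:
    """Desk-scale training schedule paired with :func:`small_model_config`.

    A slightly higher learning rate suits the narrower model; the episode
    budget (~8 x 8 x 60 episodes) trains the benchmark models in a couple of
    minutes of CPU time each.
    """
    kwargs = dict(
        lr=3e-3, batch_episodes=8, max_epochs=60, patience=60,
        episodes_per_epoch=32, query_cap=16)
    kwargs.update(overrides)
    return TrainConfig(**kwargs)
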