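"""Episodic meta-training and feed-forward few-shot adaptation.

One episode is one subject-level adaptation problem: a balanced support set
(n_shot trials per class) and a disjoint query set from the same subject.
Meta-training samples batches of episodes across training subjects, computes
prompts from each episode's support, scores the queries conditioned on those
prompts, and minimises

    L_meta = mean cross-entropy over the query set + lam * ||P_s||_F^2

jointly over theta (backbone), phi (support encoder) and psi (prompt
generator) with Adam under cosine-annealed learning rate. Validation episodes
come from one held-out training subject, rotated every epoch; early stopping
keeps the best-validation snapshot.

At test time adaptation is purely feed-forward: prompts are generated once
from the unseen subject's support set — no gradient step touches any
parameter, and query trials contribute to no statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .config import TrainConfig
from .network import TCPLNetwork
from .nn import cross_entropy

__all__ = ["Episode", "sample_episode", "meta_loss", "Adam", "cosine_lr",
           "meta_train", "adapt_and_predict", "TrainState"]

log = logging.getLogger(__name__)


@dataclass
class Episode:
    """Support/query split of one subject's trials (disjoint by construction)."""

    subject_id: str
    support_x: np.ndarray
    support_y: np.ndarray
    query_x: np.ndarray
    query_y: np.ndarray
    support_idx: np.ndarray = field(default=None)
    query_idx: np.ndarray = field(default=None)


def sample_episode(X: np.ndarray, y: np.ndarray, n_shot: int,
                   rng: np.random.Generator, subject_id: str = "?",
                   query_cap: int | None = None) -> Episode:
    """Draw n_shot support trials per class without replacement; rest are queries."""
    y = np.asarray(y)
    support_idx = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < n_shot + 1:
            raise ValueError(
                f"class {c} has {len(idx)} trials; need >= {n_shot + 1} "
                f"for an {n_shot}-shot episode with a non-empty query set")
        support_idx.append(rng.choice(idx, size=n_shot, replace=False))
    support_idx = np.sort(np.concatenate(support_idx))
    mask = np.ones(len(y), dtype=bool)
    mask[support_idx] = False
    query_idx = np.flatnonzero(mask)
    if query_cap is not None and len(query_idx) > query_cap:
        query_idx = np.sort(rng.choice(query_idx, size=query_cap, replace=False))
    return Episode(subject_id, X[support_idx], y[support_idx],
                   X[query_idx], y[query_idx], support_idx, query_idx)


def meta_loss(logits: Tensor, labels: np.ndarray, prompts: Tensor | None,
              lam: float) -> Tensor:
    """Mean query cross-entropy plus lam * squared Frobenius norm of the prompts."""
    loss = cross_entropy(logits, labels)
    if prompts is not None and lam > 0:
        loss = loss + lam * (prompts * prompts).sum()
    return loss


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay (added to grads)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(lr0: float, lr_min: float, step: int, total_steps: int) -> float:
    """Cosine annealing from lr0 to lr_min over total_steps."""
    if total_steps <= 1:
        return lr0
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return lr_min + 0.5 * (lr0 - lr_min) * (1 + np.cos(np.pi * frac))


@dataclass
class TrainState:
    """Outcome of meta-training: the trained network plus run bookkeeping."""

    network: TCPLNetwork
    history: dict
    best_epoch: int
    best_val_accuracy: float


def _episode_loss(net: TCPLNetwork, ep: Episode, lam: float) -> Tensor:
    prompts = net.prompts_from_support(ep.support_x)
    logits = net.forward(ep.query_x, prompts)
    return meta_loss(logits, ep.query_y, prompts, lam)


def _validation_accuracy(net: TCPLNetwork, X: np.ndarray, y: np.ndarray,
                         n_shot: int, rng: np.random.Generator,
                         n_episodes: int = 2, query_cap: int | None = 32) -> float:
    net.eval()
    correct = total = 0
    for _ in range(n_episodes):
        ep = sample_episode(X, y, n_shot, rng, query_cap=query_cap)
        pred, _ = adapt_and_predict(net, ep.support_x, ep.support_y, ep.query_x)
        correct += int((pred == ep.query_y).sum())
        total += len(ep.query_y)
    net.train()
    return correct / total if total else 0.0


def meta_train(subjects: dict[str, tuple[np.ndarray, np.ndarray]],
               network: TCPLNetwork, cfg: TrainConfig,
               rng: np.random.Generator) -> TrainState:
    """Episodic meta-training over the given training subjects.

    ``subjects`` maps subject id -> (X, y) with X of shape n x C x T. At least
    two subjects are required: each epoch one subject (rotating) is held out
    to provide validation episodes that mirror the test condition.
    """
    sids = sorted(subjects)
    if len(sids) < 2:
        raise ValueError("meta-training needs >= 2 subjects "
                         "(one is rotated out for validation)")
    episodes_per_epoch = cfg.episodes_per_epoch or 10 * len(sids)
    n_batches = max(1, episodes_per_epoch // cfg.batch_episodes)
    total_steps = n_batches * cfg.max_epochs

    network.train()
    network.bind_rng(rng)
    groups = network.parameter_groups()
    if cfg.freeze_backbone:
        trainable = list(groups["phi"].values()) + list(groups["psi"].values())
        if not trainable:
            raise ValueError("freeze_backbone requires an active prompt path")
    else:
        trainable = network.parameters()
    opt = Adam(trainable, lr=cfg.lr, weight_decay=cfg.weight_decay)

    history = {"batch_loss": [], "val_accuracy": [], "lr": []}
    best_state, best_val, best_epoch = None, -np.inf, -1
    bad_epochs = 0
    step = 0

    fixed_val_sid = sids[0] if cfg.validation == "fixed" else None

    for epoch in range(cfg.max_epochs):
        # fixed: one subject is held out of training entirely, so validation
        # accuracy measures cross-subject generalisation and best-snapshot
        # selection is meaningful; rotating: the held-out subject changes per
        # epoch (validation saturates, selection defaults to the last epochs)
        val_sid = fixed_val_sid if fixed_val_sid is not None \
            else sids[epoch % len(sids)]
        train_sids = [s for s in sids if s != val_sid]
        for _ in range(n_batches):
            opt.lr = cosine_lr(cfg.lr, cfg.lr_min, step, total_steps)
            batch_loss = None
            for _ in range(cfg.batch_episodes):
                sid = train_sids[rng.integers(len(train_sids))]
                X, y = subjects[sid]
                ep = sample_episode(X, y, cfg.n_shot, rng, sid,
                                    query_cap=cfg.query_cap)
                loss = _episode_loss(network, ep, cfg.lam)
                batch_loss = loss if batch_loss is None else batch_loss + loss
            batch_loss = batch_loss * (1.0 / cfg.batch_episodes)
            if not np.isfinite(batch_loss.data):
                raise RuntimeError(
                    f"meta-training diverged (non-finite loss) at epoch {epoch}, "
                    f"step {step}, lr {opt.lr:.3g}")
            opt.zero_grad()
            batch_loss.backward()
            opt.step()
            history["batch_loss"].append(float(batch_loss.data))
            history["lr"].append(opt.lr)
            step += 1

        Xv, yv = subjects[val_sid]
        val_acc = _validation_accuracy(network, Xv, yv, cfg.n_shot, rng,
                                       n_episodes=4)
        history["val_accuracy"].append(val_acc)
        log.info("epoch %d: loss %.4f, val acc %.3f (val subject %s)",
                 epoch, history["batch_loss"][-1], val_acc, val_sid)
        # ties prefer the later snapshot: the rotating validation subject is
        # seen by training in other epochs, so validation accuracy saturates
        # and the most-trained tied model generalises best
        if val_acc >= best_val:
            best_val, best_epoch = val_acc, epoch
            best_state = network.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                log.info("early stopping at epoch %d", epoch)
                break

    if best_state is not None:
        network.load_state_dict(best_state)
    network.eval()
    return TrainState(network, history, best_epoch, best_val)


def adapt_and_predict(network: TCPLNetwork, support_x: np.ndarray,
                      support_y: np.ndarray,
                      query_x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Feed-forward adaptation: prompts once from the support, then predict.

    Returns (predicted labels, class probabilities). No parameter is updated
    and no statistic is computed from the queries; an empty query list yields
    empty outputs.
    """
    if query_x is None or len(query_x) == 0:
        return (np.array([], dtype=np.int64),
                np.empty((0, network.n_classes)))
    was_training = network.training
    network.eval()
    try:
        prompts = network.prompts_from_support(support_x)
        if prompts is not None:
            prompts = prompts.detach()
        proba = network.predict_proba(np.asarray(query_x), prompts)
    finally:
        if was_training:
            network.train()
    return proba.argmax(axis=1), proba
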