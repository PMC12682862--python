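"""Cross-subject evaluation protocols: fold construction, few-shot sweeps,
robustness and ablation suites.

Subjects are partitioned into folds exactly once (ten-fold over subjects, with
+/-1 subject tolerance when counts do not divide, or leave-one-subject-out).
For each fold x seed the model is meta-trained on the training subjects and
evaluated on every held-out subject by feed-forward prompt adaptation. Support
sets are nested across shot counts within a seed (the 1-shot support is a
subset of the 5-shot support, and so on) to reduce sweep variance.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, TrainConfig
from .containers import SubjectTrials, arrays_to_trials, trials_to_arrays
from .meta import TrainState, adapt_and_predict, meta_train
from .metrics import compute_metrics, summarize
from .network import TCPLNetwork
from .simulate import add_gaussian_noise_snr, drop_channels

__all__ = ["ProtocolSpec", "make_folds", "run_protocol", "fewshot_sweep",
           "robustness_suite", "ablation_suite", "nested_support_indices"]

log = logging.getLogger(__name__)


@dataclass
class ProtocolSpec:
    mode: str = "tenfold"              # tenfold | loso
    shots: tuple[int, ...] = (5,)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_folds: int = 10

    def __post_init__(self):
        if self.mode not in ("tenfold", "loso"):
            raise ValueError("mode must be 'tenfold' or 'loso'")
        if not self.shots or min(self.shots) < 1:
            raise ValueError("shots must be a non-empty tuple of counts >= 1")


def make_folds(subject_ids: list[str], mode: str, n_folds: int = 10,
               rng: np.random.Generator | None = None
               ) -> list[tuple[list[str], list[str]]]:
    """Partition subjects into folds; every subject is tested exactly once."""
    ids = list(subject_ids)
    if mode == "loso":
        folds = [[sid] for sid in ids]
    else:
        if n_folds > len(ids):
            raise ValueError(
                f"cannot make {n_folds} folds from {len(ids)} subjects")
        order = np.array(ids, dtype=object)
        if rng is not None:
            rng.shuffle(order)
        folds = [list(chunk) for chunk in np.array_split(order, n_folds)]
    out = []
    for fold in folds:
        test = list(fold)
        train = [s for s in ids if s not in test]
        assert not set(train) & set(test), "fold train/test sets overlap"
        out.append((train, test))
    tested = [s for _, test in out for s in test]
    assert sorted(tested) == sorted(ids), "folds do not partition the subjects"
    return out


def nested_support_indices(y: np.ndarray, max_shot: int,
                           rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Per-class permutations whose prefixes give nested supports for any shot."""
    perms = {int(c): rng.permutation(np.flatnonzero(y == c))
             for c in np.unique(y)}
    if any(len(p) <= max_shot for p in perms.values()):
        raise ValueError(f"every class needs > {max_shot} trials per subject")
    return perms


def _subject_rng(base_seed: int, seed: int, subject: str) -> np.random.Generator:
    # crc32 is stable across processes (str hash is salted per interpreter)
    return np.random.default_rng(
        [base_seed, seed, zlib.crc32(subject.encode()) % (2 ** 31)])


def _evaluate_subject(net: TCPLNetwork, X: np.ndarray, y: np.ndarray,
                      shots: tuple[int, ...], rng: np.random.Generator,
                      n_classes: int) -> list[dict]:
    perms = nested_support_indices(y, max(shots), rng)
    rows = []
    for shot in shots:
        support_idx = np.sort(np.concatenate(
            [perm[:shot] for perm in perms.values()]))
        mask = np.ones(len(y), dtype=bool)
        mask[support_idx] = False
        query_idx = np.flatnonzero(mask)
        pred, _ = adapt_and_predict(net, X[support_idx], y[support_idx],
                                    X[query_idx])
        row = compute_metrics(y[query_idx], pred, n_classes)
        row.update(shot=shot, n_queries=len(query_idx),
                   support_indices=",".join(map(str, support_idx)))
        rows.append(row)
    return rows


def _train_fold(subjects: dict[str, SubjectTrials], train_ids: list[str],
                model_cfg: ModelConfig, train_cfg: TrainConfig,
                seed: int) -> TrainState:
    first = subjects[train_ids[0]]
    n_classes = int(max(int(s.labels.max()) for s in subjects.values()) + 1)
    rng = np.random.default_rng(seed)
    net = TCPLNetwork(first.data.shape[1], n_classes, first.data.shape[2],
                      model_cfg, rng)
    data = {sid: (subjects[sid].data, subjects[sid].labels) for sid in train_ids}
    return meta_train(data, net, train_cfg, rng)


def run_protocol(subjects: dict[str, SubjectTrials], spec: ProtocolSpec,
                 model_cfg: ModelConfig, train_cfg: TrainConfig,
                 base_seed: int = 0, condition: str = "clean",
                 return_models: bool = False):
    """Full protocol: folds x seeds meta-training + few-shot evaluation.

    Returns (per-row DataFrame, summary DataFrame, manifest dict) and, when
    ``return_models`` is set, a {(fold, seed): TrainState} cache for reuse by
    evaluation-only suites.
    """
    sids = sorted(subjects)
    n_classes = int(max(int(s.labels.max()) for s in subjects.values()) + 1)
    fold_rng = np.random.default_rng(base_seed)
    folds = make_folds(sids, spec.mode, spec.n_folds, fold_rng)
    rows, models = [], {}
    for fi, (train_ids, test_ids) in enumerate(folds):
        for seed in spec.seeds:
            state = _train_fold(subjects, train_ids, model_cfg, train_cfg,
                                base_seed + 1000 * seed + fi)
            if return_models:
                models[(fi, seed)] = state
            for sid in test_ids:
                sub = subjects[sid]
                srng = _subject_rng(base_seed, seed, sid)
                for row in _evaluate_subject(state.network, sub.data, sub.labels,
                                             spec.shots, srng, n_classes):
                    row.update(fold=fi, seed=seed, subject=sid,
                               condition=condition)
                    rows.append(row)
    df = pd.DataFrame(rows)
    summary = summarize(df, by=["condition", "shot"])
    manifest = {
        "mode": spec.mode, "shots": list(spec.shots),
        "seeds": list(spec.seeds), "base_seed": base_seed,
        "folds": [{"train": tr, "test": te} for tr, te in folds],
        "n_classes": n_classes,
    }
    if return_models:
        return df, summary, manifest, models
    return df, summary, manifest


def fewshot_sweep(subjects: dict[str, SubjectTrials], spec: ProtocolSpec,
                  model_cfg: ModelConfig, train_cfg: TrainConfig,
                  base_seed: int = 0):
    """Few-shot sweep: one protocol run reporting every shot count (supports
    nested across shots within each seed by construction)."""
    return run_protocol(subjects, spec, model_cfg, train_cfg, base_seed)


def _add_noise_arrays(X: np.ndarray, snr_db: float | None, seed: int) -> np.ndarray:
    trials = arrays_to_trials(X, np.zeros(len(X), dtype=int), "tmp", 1.0)
    noisy = add_gaussian_noise_snr(trials, snr_db, seed)
    Xn, _ = trials_to_arrays(noisy)
    return Xn


def robustness_suite(subjects: dict[str, SubjectTrials], spec: ProtocolSpec,
                     model_cfg: ModelConfig, train_cfg: TrainConfig,
                     snrs_db: tuple[float | None, ...] = (None, 10.0, 5.0),
                     channel_keeps: tuple[int, ...] = (),
                     base_seed: int = 0,
                     models: dict | None = None):
    """Noise and channel-reduction robustness.

    Noise is applied at evaluation time to the unseen subject's support and
    query trials only; trained models are reused across SNR conditions (and
    may be passed in via ``models``). Channel reduction is a montage change:
    the same random channel subset is applied to every subject and the model
    is retrained per keep-count.
    """
    sids = sorted(subjects)
    n_classes = int(max(int(s.labels.max()) for s in subjects.values()) + 1)
    folds = make_folds(sids, spec.mode, spec.n_folds,
                       np.random.default_rng(base_seed))
    rows = []

    if models is None:
        _, _, _, models = run_protocol(subjects, spec, model_cfg, train_cfg,
                                       base_seed, return_models=True)

    for fi, (train_ids, test_ids) in enumerate(folds):
        for seed in spec.seeds:
            state = models[(fi, seed)]
            for sid in test_ids:
                sub = subjects[sid]
                for snr in snrs_db:
                    noise_seed = base_seed + 7919 * seed + 31 * fi
                    Xn = _add_noise_arrays(sub.data, snr, noise_seed)
                    srng = _subject_rng(base_seed, seed, sid)
                    label = "clean" if snr is None or np.isinf(snr) else f"snr{snr:g}dB"
                    for row in _evaluate_subject(state.network, Xn, sub.labels,
                                                 spec.shots, srng, n_classes):
                        row.update(fold=fi, seed=seed, subject=sid,
                                   condition=label)
                        rows.append(row)

    for keep in channel_keeps:
        # montage reduction: one subset for the whole condition, then retrain
        reduced = {}
        kept = None
        for sid in sids:
            sub = subjects[sid]
            trials = arrays_to_trials(sub.data, sub.labels, sid, sub.fs)
            dropped, kept = drop_channels(trials, keep, base_seed + keep)
            Xr, yr = trials_to_arrays(dropped)
            reduced[sid] = SubjectTrials(Xr, yr, sub.fs, sid)
        df_k, _, _ = run_protocol(reduced, spec, model_cfg, train_cfg,
                                  base_seed, condition=f"keep{keep}")
        df_k["kept_channels"] = ",".join(map(str, kept))
        rows.extend(df_k.to_dict("records"))

    df = pd.DataFrame(rows)
    return df, summarize(df, by=["condition", "shot"]), models


def ablation_suite(subjects: dict[str, SubjectTrials], spec: ProtocolSpec,
                   model_cfg: ModelConfig, train_cfg: TrainConfig,
                   variants: tuple[str, ...] = ("full", "no_tcp",
                                                "no_transformer", "no_tcn"),
                   base_seed: int = 0):
    """Train and evaluate architectural variants under an identical budget."""
    import dataclasses

    frames = []
    param_counts = {}
    for variant in variants:
        cfg_v = dataclasses.replace(model_cfg, variant=variant,
                                    k=0 if variant == "no_tcp" else model_cfg.k)
        sids = sorted(subjects)
        first = subjects[sids[0]]
        probe = TCPLNetwork(first.data.shape[1], 2, first.data.shape[2], cfg_v,
                            np.random.default_rng(0))
        param_counts[variant] = probe.n_parameters()
        df, _, _ = run_protocol(subjects, spec, cfg_v, train_cfg, base_seed,
                                condition=variant)
        frames.append(df)
    log.info("ablation parameter counts: %s", param_counts)
    df = pd.concat(frames, ignore_index=True)
    return df, summarize(df, by=["condition", "shot"]), param_counts
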