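"""Bundled desk-scale benchmark experiments.

Defines the package's standard synthetic study conditions — 10 subjects, 4
motor-imagery classes, 16 channels, 40 trials per class, subject jitter 0.3,
moderate sensor noise — and helpers to meta-train and evaluate the decoder on
them on a single CPU in minutes. Epochs are 1 s (128 samples) and the reduced
architecture of :func:`tcpl.config.small_model_config` is used so a full
training run is ~1-2 minutes; every code path matches the full-size model.

Both the test suite and the results-reproduction script build on these
helpers, so the reported numbers always come from the same conditions.
"""

from __future__ import annotations

import numpy as np

from .config import TrainConfig, small_model_config, small_train_config
from .containers import SubjectTrials
from .meta import TrainState, adapt_and_predict, meta_train
from .metrics import compute_metrics
from .network import TCPLNetwork
from .simulate import BenchmarkSpec, add_gaussian_noise_snr, make_benchmark_arrays
from .evaluation import nested_support_indices, _subject_rng

__all__ = ["desk_spec", "desk_benchmark", "train_desk_model",
           "evaluate_fewshot", "evaluate_noise_robustness"]

N_TRAIN_SUBJECTS = 8
DESK_SEED = 7


def desk_spec(subject_jitter: float = 0.3, seed: int = DESK_SEED) -> BenchmarkSpec:
    """The standard desk-scale benchmark conditions."""
    return BenchmarkSpec(n_subjects=10, n_classes=4, n_channels=16,
                         trials_per_class=40, epoch_s=1.0,
                         subject_jitter=subject_jitter, noise_sigma=0.5,
                         erd_gain=0.3, seed=seed)


def desk_benchmark(subject_jitter: float = 0.3,
                   seed: int = DESK_SEED) -> dict[str, SubjectTrials]:
    return make_benchmark_arrays(desk_spec(subject_jitter, seed))


def split_subjects(subjects: dict[str, SubjectTrials]) -> tuple[list[str], list[str]]:
    sids = sorted(subjects)
    return sids[:N_TRAIN_SUBJECTS], sids[N_TRAIN_SUBJECTS:]


def train_desk_model(subjects: dict[str, SubjectTrials], train_ids: list[str],
                     variant: str = "full", seed: int = 0,
                     n_shot: int = 10,
                     train_cfg: TrainConfig | None = None) -> TrainState:
    """Meta-train the reduced model on the given training subjects."""
    cfg = small_model_config(variant=variant,
                             k=0 if variant == "no_tcp" else 4)
    tc = train_cfg or small_train_config(n_shot=n_shot)
    first = subjects[train_ids[0]]
    n_classes = int(max(int(s.labels.max()) for s in subjects.values()) + 1)
    rng = np.random.default_rng(seed)
    net = TCPLNetwork(first.data.shape[1], n_classes, first.data.shape[2],
                      cfg, rng)
    data = {sid: (subjects[sid].data, subjects[sid].labels)
            for sid in train_ids}
    return meta_train(data, net, tc, rng)


def evaluate_fewshot(net: TCPLNetwork, subjects: dict[str, SubjectTrials],
                     test_ids: list[str], shots: tuple[int, ...],
                     seed: int, snr_db: float | None = None,
                     n_draws: int = 1) -> list[dict]:
    """Few-shot evaluation with nested supports; optional test-time noise.

    Noise (when requested) is applied to the unseen subject's support and
    query trials only. ``n_draws`` independent support draws per subject
    reduce evaluation variance (the support draw determines the prompts and
    the support/query split). Returns one row per (subject, draw, shot) with
    metrics and raw correct/total counts for exact binomial pooling.
    """
    n_classes = net.n_classes
    rows = []
    for sid in test_ids:
        sub = subjects[sid]
        X, y = sub.data, sub.labels
        if snr_db is not None and not np.isinf(snr_db):
            from .containers import arrays_to_trials, trials_to_arrays

            noisy = add_gaussian_noise_snr(
                arrays_to_trials(X, y, sid, sub.fs), snr_db,
                seed=seed * 131 + 17)
            X, _ = trials_to_arrays(noisy)
        srng = _subject_rng(DESK_SEED, seed, sid)
        for draw in range(n_draws):
            perms = nested_support_indices(y, max(shots), srng)
            for shot in shots:
                support_idx = np.sort(np.concatenate(
                    [perm[:shot] for perm in perms.values()]))
                mask = np.ones(len(y), dtype=bool)
                mask[support_idx] = False
                query_idx = np.flatnonzero(mask)
                pred, _ = adapt_and_predict(net, X[support_idx],
                                            y[support_idx], X[query_idx])
                row = compute_metrics(y[query_idx], pred, n_classes)
                row.update(subject=sid, shot=shot, seed=seed, draw=draw,
                           n_correct=int((pred == y[query_idx]).sum()),
                           n_queries=len(query_idx))
                rows.append(row)
    return rows


def evaluate_noise_robustness(net: TCPLNetwork,
                              subjects: dict[str, SubjectTrials],
                              test_ids: list[str], shot: int, seed: int,
                              snrs_db=(None, 10.0, 5.0),
                              n_draws: int = 1) -> dict[str, list[dict]]:
    out = {}
    for snr in snrs_db:
        label = "clean" if snr is None or np.isinf(snr) else f"snr{snr:g}dB"
        out[label] = evaluate_fewshot(net, subjects, test_ids, (shot,), seed,
                                      snr_db=snr, n_draws=n_draws)
    return out
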