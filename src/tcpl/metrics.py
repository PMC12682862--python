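"""Classification metrics for cross-subject decoding reports.

Accuracy, Cohen's kappa, macro-F1 and macro-recall, all reported in percent,
aggregated as mean +/- std over folds x seeds.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, cohen_kappa_score, f1_score,
                             recall_score)

__all__ = ["compute_metrics", "summarize"]

log = logging.getLogger(__name__)

METRIC_COLUMNS = ["accuracy", "kappa", "macro_f1", "macro_recall"]


def compute_metrics(y_true, y_pred, n_classes: int) -> dict[str, float]:
    """One metrics row (percent scale) for a pair of label sequences."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("label sequences must be non-empty and equal length")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    labels = np.arange(n_classes)
    if len(np.unique(y_true)) < n_classes:
        log.warning("some classes absent from y_true; macro averages treat "
                    "undefined per-class scores as 0")
    return {
        "accuracy": 100.0 * accuracy_score(y_true, y_pred),
        "kappa": 100.0 * cohen_kappa_score(y_true, y_pred, labels=labels),
        "macro_f1": 100.0 * f1_score(y_true, y_pred, labels=labels,
                                     average="macro", zero_division=0),
        "macro_recall": 100.0 * recall_score(y_true, y_pred, labels=labels,
                                             average="macro", zero_division=0),
    }


def summarize(rows: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Mean +/- std of every metric column over folds x seeds.

    Groups with a single row get std 0 and are flagged (``degenerate_std``).
    """
    agg = rows.groupby(by, dropna=False)[METRIC_COLUMNS].agg(["mean", "std", "count"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    for m in METRIC_COLUMNS:
        agg[f"{m}_std"] = agg[f"{m}_std"].fillna(0.0)
    agg["degenerate_std"] = agg[f"{METRIC_COLUMNS[0]}_count"] <= 1
    return agg.reset_index()
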