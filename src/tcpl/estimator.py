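"""Scikit-learn-style estimator wrapping the full meta-learning pipeline.

``TCPLClassifier.fit(X, y, groups)`` meta-trains the prompt-conditioned
TCN-Transformer over the subjects given by ``groups``; ``adapt`` generates
prompt tokens from a new subject's few labelled calibration trials; and
``predict``/``predict_proba`` score that subject's remaining trials. The
estimator composes with sklearn model selection through the standard
``get_params``/``set_params`` machinery.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import ModelConfig, TrainConfig
from .meta import adapt_and_predict, meta_train
from .network import TCPLNetwork

__all__ = ["TCPLClassifier"]


class TCPLClassifier(BaseEstimator, ClassifierMixin):
    """Few-shot cross-subject motor-imagery decoder.

    Parameters mirror the published recipe: ``k`` prompt tokens of dimension
    ``d`` generated from a support set, a causal dilated TCN backbone, a
    prompt-prefixed Transformer encoder and episodic meta-training with the
    prompt-norm-regularised query cross-entropy.

    Examples
    --------
    >>> clf = TCPLClassifier(max_epochs=2, episodes_per_epoch=8)
    >>> clf.fit(X_train, y_train, groups=subject_ids)   # doctest: +SKIP
    >>> clf.adapt(X_support, y_support)                 # doctest: +SKIP
    >>> y_hat = clf.predict(X_query)                    # doctest: +SKIP
    """

    def __init__(self, *, k=10, d=64, tcn_kernel=3, tcn_dilations=(1, 2, 4, 8),
                 tcn_widths=(64, 64, 128, 128), tcn_dropout=0.1, pool_stride=2,
                 transformer_layers=4, heads=8, ffn_dim=256,
                 transformer_dropout=0.1, positional="learned",
                 head_pooling="sequence", variant="full",
                 lr=1e-3, lr_min=0.0, weight_decay=1e-4, batch_episodes=16,
                 max_epochs=100, patience=10, episodes_per_epoch=None,
                 n_shot=5, lam=1e-4, query_cap=None, freeze_backbone=False,
                 random_state=0):
        self.k = k
        self.d = d
        self.tcn_kernel = tcn_kernel
        self.tcn_dilations = tcn_dilations
        self.tcn_widths = tcn_widths
        self.tcn_dropout = tcn_dropout
        self.pool_stride = pool_stride
        self.transformer_layers = transformer_layers
        self.heads = heads
        self.ffn_dim = ffn_dim
        self.transformer_dropout = transformer_dropout
        self.positional = positional
        self.head_pooling = head_pooling
        self.variant = variant
        self.lr = lr
        self.lr_min = lr_min
        self.weight_decay = weight_decay
        self.batch_episodes = batch_episodes
        self.max_epochs = max_epochs
        self.patience = patience
        self.episodes_per_epoch = episodes_per_epoch
        self.n_shot = n_shot
        self.lam = lam
        self.query_cap = query_cap
        self.freeze_backbone = freeze_backbone
        self.random_state = random_state

    # ------------------------------------------------------------------ build

    def _configs(self) -> tuple[ModelConfig, TrainConfig]:
        model_fields = {f.name for f in dataclasses.fields(ModelConfig)}
        train_fields = {f.name for f in dataclasses.fields(TrainConfig)}
        params = self.get_params()
        model_cfg = ModelConfig(**{k: v for k, v in params.items()
                                   if k in model_fields})
        train_cfg = TrainConfig(**{k: v for k, v in params.items()
                                   if k in train_fields})
        return model_cfg, train_cfg

    # -------------------------------------------------------------------- fit

    def fit(self, X, y, groups=None):
        """Meta-train on trials (n, C, T) labelled by class ``y`` and subject
        ``groups`` (one episode distribution per subject)."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be n_trials x channels x samples")
        if groups is None:
            raise ValueError("groups (subject ids) are required: episodes are "
                             "sampled within subjects")
        groups = np.asarray(groups)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        model_cfg, train_cfg = self._configs()
        rng = np.random.default_rng(self.random_state)
        net = TCPLNetwork(X.shape[1], len(self.classes_), X.shape[2],
                          model_cfg, rng)
        subjects = {str(sid): (X[groups == sid], y_enc[groups == sid])
                    for sid in np.unique(groups)}
        state = meta_train(subjects, net, train_cfg, rng)
        self.network_ = state.network
        self.history_ = state.history
        self.best_epoch_ = state.best_epoch
        self.n_features_in_ = X.shape[1] * X.shape[2]
        self.prompts_ = None
        return self

    # ----------------------------------------------------------------- adapt

    def adapt(self, X_support, y_support):
        """Generate prompts once from an unseen subject's calibration trials."""
        check_is_fitted(self, "network_")
        X_support = np.asarray(X_support, dtype=np.float64)
        self._support_ = (X_support, np.asarray(y_support))
        prompts = self.network_.prompts_from_support(X_support)
        self.prompts_ = None if prompts is None else prompts.detach()
        return self

    # --------------------------------------------------------------- predict

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=np.float64)
        if len(X) == 0:
            return np.empty((0, len(self.classes_)))
        if self.network_.has_tcp and self.prompts_ is None:
            raise RuntimeError("call adapt(X_support, y_support) before "
                               "predicting with an active prompt path")
        self.network_.eval()
        return self.network_.predict_proba(X, self.prompts_)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)] if len(proba) else \
            np.array([], dtype=self.classes_.dtype)

    def adapt_predict(self, X_support, y_support, X_query):
        """Convenience: one-call feed-forward adaptation + prediction."""
        check_is_fitted(self, "network_")
        pred, proba = adapt_and_predict(self.network_,
                                        np.asarray(X_support, dtype=np.float64),
                                        np.asarray(y_support),
                                        np.asarray(X_query, dtype=np.float64))
        return self.classes_[pred], proba
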