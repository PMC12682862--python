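"""Episodic meta-learning: episode sampling, loss analytics, training
contracts, feed-forward adaptation."""

import numpy as np
import pytest

from tcpl.autograd import Tensor
from tcpl.config import TrainConfig, small_model_config
from tcpl.meta import (Adam, adapt_and_predict, cosine_lr, meta_loss,
                       meta_train, sample_episode)
from tcpl.network import TCPLNetwork


class TestSampleEpisode:
    def _data(self, per_class=40, n_classes=4):
        y = np.repeat(np.arange(n_classes), per_class)
        X = np.zeros((len(y), 2, 8))
        X[:, 0, 0] = np.arange(len(y))  # identify trials
        return X, y

    def test_counts_and_disjointness(self):
        X, y = self._data()
        ep = sample_episode(X, y, 5, np.random.default_rng(0))
        assert len(ep.support_y) == 20
        assert len(ep.query_y) == 140
        assert not set(ep.support_idx) & set(ep.query_idx)
        assert (np.bincount(ep.support_y) == 5).all()

    def test_one_shot(self):
        X, y = self._data()
        ep = sample_episode(X, y, 1, np.random.default_rng(1))
        assert (np.bincount(ep.support_y) == 1).all()

    def test_no_query_left_raises(self):
        X, y = self._data(per_class=40)
        with pytest.raises(ValueError, match="class"):
            sample_episode(X, y, 40, np.random.default_rng(2))

    def test_reproducible_given_rng(self):
        X, y = self._data()
        e1 = sample_episode(X, y, 5, np.random.default_rng(3))
        e2 = sample_episode(X, y, 5, np.random.default_rng(3))
        assert np.array_equal(e1.support_idx, e2.support_idx)

    def test_query_cap(self):
        X, y = self._data()
        ep = sample_episode(X, y, 5, np.random.default_rng(4), query_cap=16)
        assert len(ep.query_y) == 16


class TestMetaLoss:
    def test_uniform_logits_give_log_n_classes(self):
        logits = Tensor(np.zeros((10, 4)))
        labels = np.random.default_rng(0).integers(0, 4, 10)
        loss = meta_loss(logits, labels, None, lam=0.0)
        assert abs(loss.data - np.log(4)) < 1e-12

    def test_confident_correct_logits_drive_loss_to_zero(self):
        labels = np.array([0, 1, 2, 3])
        logits = np.full((4, 4), -50.0)
        logits[np.arange(4), labels] = 50.0
        loss = meta_loss(Tensor(logits), labels, None, lam=0.0)
        assert loss.data < 1e-12

    def test_prompt_penalty_arithmetic(self):
        # all-ones 10x64 prompts at lam=1e-4 add exactly 0.064
        labels = np.array([0])
        logits = np.array([[50.0, -50.0]])
        prompts = Tensor(np.ones((10, 64)))
        loss = meta_loss(Tensor(logits), labels, prompts, lam=1e-4)
        assert abs(loss.data - 0.064) < 1e-12

    def test_mean_not_sum_over_queries(self):
        logits = Tensor(np.zeros((7, 4)))
        labels = np.zeros(7, dtype=int)
        loss = meta_loss(logits, labels, None, lam=0.0)
        assert abs(loss.data - np.log(4)) < 1e-12  # independent of count


class TestCosineSchedule:
    def test_endpoints(self):
        assert cosine_lr(1e-3, 0.0, 0, 100) == pytest.approx(1e-3)
        assert cosine_lr(1e-3, 0.0, 99, 100) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decay(self):
        vals = [cosine_lr(1.0, 0.0, t, 50) for t in range(50)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


def _benchmark_data(tiny_benchmark):
    return {sid: (s.data, s.labels) for sid, s in tiny_benchmark.items()}


class TestMetaTrain:
    def test_zero_lr_leaves_parameters_unchanged(self, tiny_benchmark):
        cfg = small_model_config()
        tc = TrainConfig(lr=1e-30, batch_episodes=2, max_epochs=1,
                         episodes_per_epoch=2, n_shot=2, query_cap=4)
        rng = np.random.default_rng(0)
        first = next(iter(tiny_benchmark.values()))
        net = TCPLNetwork(first.data.shape[1], 4, first.data.shape[2], cfg, rng)
        before = {k: v.copy() for k, v in net.state_dict().items()}
        meta_train(_benchmark_data(tiny_benchmark), net, tc, rng)
        after = net.state_dict()
        # an effectively-zero lr changes nothing beyond floating dust
        for k in before:
            assert np.allclose(before[k], after[k], atol=1e-12)

    def test_single_subject_rejected(self, tiny_benchmark):
        sid, s = next(iter(tiny_benchmark.items()))
        cfg = small_model_config()
        net = TCPLNetwork(s.data.shape[1], 4, s.data.shape[2], cfg,
                          np.random.default_rng(0))
        with pytest.raises(ValueError, match="subjects"):
            meta_train({sid: (s.data, s.labels)}, net,
                       TrainConfig(max_epochs=1), np.random.default_rng(0))

    def test_loss_trajectory_reproducible(self, tiny_benchmark):
        data = _benchmark_data(tiny_benchmark)
        cfg = small_model_config()
        first = next(iter(tiny_benchmark.values()))
        histories = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            net = TCPLNetwork(first.data.shape[1], 4, first.data.shape[2],
                              cfg, rng)
            tc = TrainConfig(batch_episodes=2, max_epochs=2, patience=5,
                             episodes_per_epoch=4, n_shot=2, query_cap=4)
            state = meta_train(data, net, tc, rng)
            histories.append(state.history["batch_loss"])
        assert histories[0] == histories[1]

    def test_joint_update_of_all_parameter_groups(self, tiny_benchmark):
        # after one batch with lam > 0, theta, phi and psi all move
        data = _benchmark_data(tiny_benchmark)
        cfg = small_model_config()
        first = next(iter(tiny_benchmark.values()))
        rng = np.random.default_rng(3)
        net = TCPLNetwork(first.data.shape[1], 4, first.data.shape[2], cfg, rng)
        before = {g: {k: v.data.copy() for k, v in params.items()}
                  for g, params in net.parameter_groups().items()}
        tc = TrainConfig(batch_episodes=2, max_epochs=1, episodes_per_epoch=2,
                         n_shot=2, query_cap=4, lam=1e-4, patience=1)
        meta_train(data, net, tc, rng)
        for group, params in net.parameter_groups().items():
            deltas = [np.abs(params[k].data - before[group][k]).max()
                      for k in params]
            assert max(deltas) > 0, f"group {group} received no update"

    def test_training_loss_decreases_on_separable_benchmark(self, tiny_trained):
        losses = tiny_trained.history["batch_loss"]
        assert losses[-1] < losses[0]

    def test_freeze_backbone_only_updates_prompt_path(self, tiny_benchmark):
        data = _benchmark_data(tiny_benchmark)
        cfg = small_model_config()
        first = next(iter(tiny_benchmark.values()))
        rng = np.random.default_rng(4)
        net = TCPLNetwork(first.data.shape[1], 4, first.data.shape[2], cfg, rng)
        theta_before = {k: v.data.copy()
                        for k, v in net.parameter_groups()["theta"].items()}
        tc = TrainConfig(batch_episodes=2, max_epochs=1, episodes_per_epoch=2,
                         n_shot=2, query_cap=4, freeze_backbone=True, patience=1)
        meta_train(data, net, tc, rng)
        for k, v in net.parameter_groups()["theta"].items():
            assert np.array_equal(v.data, theta_before[k])


class TestAdaptAndPredict:
    def test_pure_function_and_no_mutation(self, tiny_trained, tiny_benchmark):
        net = tiny_trained.network
        sid, sub = sorted(tiny_benchmark.items())[0]
        ep = sample_episode(sub.data, sub.labels, 2, np.random.default_rng(0))
        checksum = {k: v.copy() for k, v in net.state_dict().items()}
        p1, proba1 = adapt_and_predict(net, ep.support_x, ep.support_y,
                                       ep.query_x)
        p2, proba2 = adapt_and_predict(net, ep.support_x, ep.support_y,
                                       ep.query_x)
        assert np.array_equal(p1, p2)
        assert np.array_equal(proba1, proba2)
        for k, v in net.state_dict().items():
            assert np.array_equal(v, checksum[k]), "adaptation mutated parameters"

    def test_probabilities_normalised(self, tiny_trained, tiny_benchmark):
        net = tiny_trained.network
        _, sub = sorted(tiny_benchmark.items())[0]
        ep = sample_episode(sub.data, sub.labels, 2, np.random.default_rng(1))
        _, proba = adapt_and_predict(net, ep.support_x, ep.support_y, ep.query_x)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_empty_query_list(self, tiny_trained, tiny_benchmark):
        net = tiny_trained.network
        _, sub = sorted(tiny_benchmark.items())[0]
        ep = sample_episode(sub.data, sub.labels, 2, np.random.default_rng(2))
        pred, proba = adapt_and_predict(net, ep.support_x, ep.support_y,
                                        np.empty((0, *sub.data.shape[1:])))
        assert len(pred) == 0 and proba.shape == (0, 4)


class TestLambdaLimit:
    def test_prompt_norm_shrinks_as_lambda_grows(self, tiny_benchmark):
        data = _benchmark_data(tiny_benchmark)
        cfg = small_model_config()
        first = next(iter(tiny_benchmark.values()))
        norms = []
        for lam in (0.0, 0.05, 1.0):
            rng = np.random.default_rng(11)
            net = TCPLNetwork(first.data.shape[1], 4, first.data.shape[2],
                              cfg, rng)
            tc = TrainConfig(batch_episodes=4, max_epochs=3, patience=5,
                             episodes_per_epoch=8, n_shot=2, query_cap=6,
                             lam=lam)
            meta_train(data, net, tc, rng)
            sub = first
            prompts = net.prompts_from_support(sub.data[:8])
            norms.append(float(np.sqrt((prompts.data ** 2).sum())))
        assert norms[0] > norms[1] > norms[2], \
            f"prompt norms {norms} not shrinking in lambda"
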