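"""Objective decomposition, metrics against rank-statistic oracles, and the
bag-at-a-time SGD loop."""

import numpy as np
import pytest
from scipy.stats import rankdata

from conftest import tiny_bags
from sparsemil.aggregation import RegularizerWeights
from sparsemil.models import assemble_model
from sparsemil.training import (
    TrainConfig,
    bag_loss,
    evaluate,
    reverse_class_weights,
    sweep_learning_rates,
    train_model,
)


def mann_whitney_auc(labels, scores):
    """Independent AUC oracle: normalized Mann-Whitney U with average ranks."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestClassWeights:
    def test_study_scale_counts(self):
        w = reverse_class_weights(214, 632)
        assert w.w_neg == pytest.approx(846 / 428)   # 1.97664
        assert w.w_pos == pytest.approx(846 / 1264)  # 0.66930
        assert (w.w_neg * 214 + w.w_pos * 632) == pytest.approx(846)

    def test_balanced_counts_give_unit_weights(self):
        w = reverse_class_weights(50, 50)
        assert w.w_neg == w.w_pos == 1.0

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            reverse_class_weights(1, 0)


class TestBagLoss:
    def test_cross_entropy_value(self):
        b = bag_loss(0.5, 1, 1.0)
        assert b.loss_no_reg == pytest.approx(np.log(2), abs=1e-12)
        assert b.loss_reg == b.loss_no_reg

    def test_l0_on_sparse_attention(self):
        reg = RegularizerWeights(lambda_l0=0.01)
        b = bag_loss(0.9, 1, 1.0, attention=np.array([1.0, 0.0]), reg=reg)
        assert b.r_l0 == pytest.approx(0.01)
        assert b.r_mer == 0.0

    def test_zero_lambdas_degenerate(self):
        reg = RegularizerWeights()
        b = bag_loss(0.3, 0, 2.0, attention=np.array([0.5, 0.5]), reg=reg)
        assert b.loss_reg == b.loss_no_reg == pytest.approx(-2.0 * np.log(0.7))

    def test_additivity(self, rng):
        from sparsemil.aggregation import softmax_transform
        for _ in range(20):
            reg = RegularizerWeights(lambda_l0=rng.uniform(0, 0.1),
                                     lambda_mer=rng.uniform(0, 0.1),
                                     mer_sign=rng.choice([-1, 1]))
            a = softmax_transform(rng.normal(0, 2, 5))
            b = bag_loss(rng.uniform(0.01, 0.99), int(rng.integers(2)),
                         rng.uniform(0.5, 2), attention=a, reg=reg)
            assert abs(b.loss_reg - (b.loss_no_reg + b.r_l0 + b.r_mer)) < 1e-9


class TestEvaluate:
    def test_perfect_ranking(self):
        r = evaluate(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0]))
        assert (r.roc_auc, r.accuracy, r.recall, r.precision, r.f1) == (1, 1, 1, 1, 1)
        np.testing.assert_array_equal(r.confusion, [[1, 0], [0, 2]])

    def test_anti_ordered_scores(self):
        r = evaluate(np.array([0.1, 0.2, 0.9]), np.array([1, 1, 0]))
        assert r.roc_auc == 0.0

    def test_tied_scores_half_credit(self):
        r = evaluate(np.array([0.4, 0.4, 0.4, 0.4]), np.array([0, 1, 0, 1]))
        assert r.roc_auc == pytest.approx(0.5, abs=1e-12)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(0, 1, n), int(rng.integers(1, 4)))
            r = evaluate(scores, labels)
            assert abs(r.roc_auc - mann_whitney_auc(labels, scores)) < 1e-12

    def test_single_class_auc_undefined(self):
        r = evaluate(np.array([0.4, 0.6]), np.array([1, 1]))
        assert np.isnan(r.roc_auc)
        assert r.recall == 0.5

    def test_f1_is_harmonic_mean(self):
        r = evaluate(np.array([0.9, 0.2, 0.7, 0.6]), np.array([1, 1, 0, 1]))
        expected = 2 * r.precision * r.recall / (r.precision + r.recall)
        assert r.f1 == pytest.approx(expected, abs=1e-12)


class TestTrainLoop:
    def test_zero_epochs_leaves_weights_untouched(self):
        bags = tiny_bags(4)
        model = assemble_model("IMIL_A", 32, seed=0)
        before = model.get_weights()
        history = train_model(model, bags, [], TrainConfig(epochs=0))
        assert history.epochs == [] and history.steps == []
        for a, b in zip(before, model.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_single_class_training_rejected(self):
        bags = [b for b in tiny_bags(4) if b.label == 1]
        model = assemble_model("IMIL_A", 32, seed=0)
        with pytest.raises(ValueError):
            train_model(model, bags, [], TrainConfig(epochs=1))

    def test_deterministic_histories(self):
        bags = tiny_bags(6)
        losses = []
        for _ in range(2):
            model = assemble_model("IMIL_SA", 32, seed=3)
            h = train_model(model, bags[:4], bags[4:], TrainConfig(epochs=2, seed=9))
            losses.append([s.loss_reg for s in h.steps])
        assert losses[0] == losses[1]

    def test_overfits_two_bag_toy_problem(self):
        """Capacity check: IMIL_A drives training accuracy to 1 on 2 bags."""
        bags = tiny_bags(2, seed=5)
        model = assemble_model("IMIL_A", 32, seed=1)
        train_model(model, bags, [], TrainConfig(epochs=50, learning_rate=0.01, seed=2))
        report = evaluate(model, bags)
        assert report.accuracy == 1.0
        # flip augmentation saw flipped copies during training: they must
        # classify identically well
        flipped = [type(b)(patches=np.ascontiguousarray(b.patches[:, ::-1, ::-1, :]),
                           label=b.label, grid_shape=b.grid_shape) for b in bags]
        assert evaluate(model, flipped).accuracy == 1.0

    def test_eq3_additivity_on_every_step(self):
        reg = RegularizerWeights(lambda_l0=0.005, lambda_mer=0.005)
        bags = tiny_bags(6)
        model = assemble_model("IMIL_SA", 32, reg=reg, seed=4)
        h = train_model(model, bags, [], TrainConfig(epochs=2, seed=0))
        assert len(h.steps) == 12
        for s in h.steps:
            assert abs(s.loss_reg - (s.loss_no_reg + s.r_l0 + s.r_mer)) < 1e-9


class TestSweep:
    def test_single_point_grid(self):
        bags = tiny_bags(6)
        factory = lambda: assemble_model("IMIL_A", 32, seed=0)
        table, model, history = sweep_learning_rates(
            factory, bags[:4], bags[4:], (0.01,), TrainConfig(epochs=1))
        assert len(table) == 1 and table[0]["lr"] == 0.01

    def test_winner_has_max_val_auc(self):
        bags = tiny_bags(8)
        factory = lambda: assemble_model("IMIL_A", 32, seed=0)
        cfg = TrainConfig(epochs=2, seed=3)
        table, model, history = sweep_learning_rates(
            factory, bags[:6], bags[6:], (1e-4, 1e-2), cfg)
        best = max(t["best_val_auc"] for t in table)
        assert history.best_val_auc == best

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_learning_rates(lambda: None, [], [], (), TrainConfig())
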