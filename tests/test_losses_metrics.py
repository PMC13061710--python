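import numpy as np
import pytest

from histossm.autograd import Tensor
from histossm.losses_metrics import (ConfusionCounts, accuracy, auc_roc,
                                     confusion, cross_entropy, error_map,
                                     evaluate_predictions, f1_score, precision,
                                     recall, total_loss, ual_loss)


class TestCrossEntropy:
    def test_perfect_prediction(self):
        assert cross_entropy(1.0, 1) < 1e-6
        assert cross_entropy(0.0, 0) < 1e-6

    def test_half_probability_is_ln2(self):
        assert cross_entropy(0.5, 1) == pytest.approx(np.log(2.0), abs=1e-9)
        assert cross_entropy(0.5, 1) == pytest.approx(0.6931, abs=1e-4)

    def test_label_smoothing_strictly_positive_at_perfect(self):
        assert cross_entropy(1.0, 1, label_smoothing=0.1) > 0.1

    def test_label_smoothing_target_formula(self):
        # loss = -[t ln p + (1-t) ln(1-p)] with t = (1-s) y + s/2
        s, p = 0.2, 0.7
        t = (1 - s) * 1.0 + s / 2
        expected = -(t * np.log(p) + (1 - t) * np.log(1 - p))
        assert cross_entropy(p, 1, label_smoothing=s) == pytest.approx(expected)

    def test_class_weights(self):
        base = cross_entropy(0.4, 1)
        assert cross_entropy(0.4, 1, class_weights=(1.0, 2.0)) == pytest.approx(2 * base)

    def test_batch_mean(self):
        got = cross_entropy(np.array([0.5, 0.5]), np.array([1, 0]))
        assert got == pytest.approx(np.log(2.0))

    def test_tensor_path_differentiable(self):
        p = Tensor(np.array([0.3, 0.8]), requires_grad=True)
        loss = cross_entropy(p, np.array([0, 1]))
        loss.backward()
        # d/dp of -(1-y)ln(1-p) at y=0, p=0.3 is 1/(1-p)/N
        assert p.grad[0] == pytest.approx(1 / 0.7 / 2, rel=1e-6)


class TestErrorMap:
    def test_perfect_local_prediction(self):
        np.testing.assert_allclose(error_map(np.ones((3, 3)), 1), 0.0)

    def test_constant_case(self):
        np.testing.assert_allclose(error_map(np.full((2, 2), 0.3), 0), 0.3)

    def test_entrywise(self):
        np.testing.assert_allclose(error_map(np.array([[0.2, 0.9]]), 1),
                                   [[0.8, 0.1]], atol=1e-12)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            error_map(np.array([[1.2]]), 1)


class TestUalLoss:
    def test_positive_affine_gives_zero(self, rng):
        u = rng.random((8, 8))
        e = 2.0 * u + 0.1
        assert ual_loss(u, e) == pytest.approx(0.0, abs=1e-9)

    def test_negative_affine_gives_two(self, rng):
        u = rng.random((8, 8))
        assert ual_loss(u, 1.0 - u) == pytest.approx(2.0, abs=1e-9)

    def test_independent_noise_near_one(self):
        rng = np.random.default_rng(0)
        u = rng.random((100, 100))
        e = rng.random((100, 100))
        assert 0.95 <= ual_loss(u, e) <= 1.05

    def test_zero_variance_is_neutral(self):
        assert ual_loss(np.full((4, 4), 0.3), np.random.rand(4, 4)) == 1.0

    def test_bounded(self, rng):
        for _ in range(20):
            val = ual_loss(rng.random((6, 6)), rng.random((6, 6)))
            assert 0.0 <= val <= 2.0

    def test_affine_invariance(self, rng):
        u = rng.random((10, 10))
        e = rng.random((10, 10))
        base = ual_loss(u, e)
        assert ual_loss(3.0 * u + 1.0, e) == pytest.approx(base, abs=1e-9)
        assert ual_loss(u, 0.5 * e + 0.2) == pytest.approx(base, abs=1e-9)

    def test_spearman_monotone_relation_is_zero(self, rng):
        u = rng.random((8, 8))
        assert ual_loss(u, u**3, metric="spearman") == pytest.approx(0.0, abs=1e-9)

    def test_mse_identical_maps_zero(self, rng):
        u = rng.random((5, 5))
        assert ual_loss(u, 2.0 * u + 0.3, metric="mse") == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_and_unknown_metric(self, rng):
        with pytest.raises(ValueError):
            ual_loss(rng.random((3, 3)), rng.random((4, 4)))
        with pytest.raises(ValueError):
            ual_loss(rng.random((3, 3)), rng.random((3, 3)), metric="kendall")


class TestTotalLoss:
    def test_gamma_zero(self):
        assert total_loss(1.7, 0.9, gamma=0.0).total == pytest.approx(1.7)

    def test_weighted_sum(self):
        assert total_loss(1.0, 1.0, gamma=0.1).total == pytest.approx(1.1)

    def test_gradient_decomposition(self, rng):
        """grad(total) = grad(cel) + gamma * grad(ual) through autodiff."""
        local = rng.random((4, 4)) * 0.8 + 0.1
        u = rng.random((4, 4))

        def grads(with_ual_only, with_cel_only):
            p = Tensor(local.copy(), requires_grad=True)
            cel = cross_entropy(p.mean(), 1)
            ual = ual_loss(Tensor(u), error_map(p, 1))
            if with_cel_only:
                loss = cel
            elif with_ual_only:
                loss = ual
            else:
                loss = cel + 0.1 * ual
            loss.backward()
            return p.grad

        g_total = grads(False, False)
        g_cel = grads(False, True)
        g_ual = grads(True, False)
        np.testing.assert_allclose(g_total, g_cel + 0.1 * g_ual, atol=1e-10)


class TestMetrics:
    def test_all_correct(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert accuracy(c) == precision(c) == recall(c) == f1_score(c) == 1.0

    def test_constructed_counts(self):
        c = ConfusionCounts(tp=50, tn=40, fp=5, fn=5)
        assert accuracy(c) == pytest.approx(0.9)
        assert precision(c) == pytest.approx(10 / 11)
        assert recall(c) == pytest.approx(10 / 11)
        assert f1_score(c) == pytest.approx(10 / 11)

    def test_degenerate_denominator_returns_zero(self):
        c = ConfusionCounts(tp=0, tn=10, fp=0, fn=0)
        assert precision(c) == 0.0
        assert f1_score(c) == 0.0

    def test_f1_is_harmonic_mean(self, rng):
        pred = rng.integers(0, 2, 200)
        true = rng.integers(0, 2, 200)
        c = confusion(pred, true)
        p, r = precision(c), recall(c)
        if p + r > 0:
            assert f1_score(c) == pytest.approx(2 * p * r / (p + r))

    def test_counts_sum(self, rng):
        pred = rng.integers(0, 2, 77)
        true = rng.integers(0, 2, 77)
        assert confusion(pred, true).total == 77

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestAuc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc_roc([0.5] * 10, [1, 0] * 5) == pytest.approx(0.5)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert 0.48 <= auc_roc(scores, labels) <= 0.52

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        assert auc_roc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.9], [1, 1])


def test_evaluate_predictions_bundle(rng):
    scores = rng.random(100)
    labels = (scores + rng.normal(0, 0.2, 100) > 0.5).astype(int)
    out = evaluate_predictions(scores, labels)
    c = out["confusion"]
    assert c["tp"] + c["tn"] + c["fp"] + c["fn"] == 100
    p, r = out["precision"], out["recall"]
    if p + r > 0:
        assert out["f1"] == pytest.approx(2 * p * r / (p + r))
    assert 0.5 < out["auc_roc"] <= 1.0
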