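"""Loss worked values, confusion-matrix metrics, and the brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lodgeseg import losses as ls
from lodgeseg import metrics as mx


class TestFocalLoss:
    def test_perfect_confidence_gives_zero(self):
        assert ls.focal_loss(np.ones(10)) == 0.0

    def test_half_confidence_worked_value(self):
        assert ls.focal_loss(np.array([0.5]), gamma=2.0) == pytest.approx(
            -0.25 * math.log(0.5), rel=1e-12
        )
        assert ls.focal_loss(np.array([0.5]), gamma=2.0) == pytest.approx(0.17329, abs=1e-5)

    def test_gamma_zero_is_cross_entropy(self):
        pt = np.array([0.3, 0.8, 0.99])
        assert ls.focal_loss(pt, gamma=0.0) == pytest.approx(float(np.mean(-np.log(pt))))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            ls.focal_loss(np.array([1.2]))


class TestDiceLoss:
    def test_identical_masks_give_zero(self):
        mask = np.array([1.0, 0.0, 1.0, 1.0])
        assert ls.dice_loss(mask, mask) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_masks_give_one(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 1.0])
        assert ls.dice_loss(a, b) == pytest.approx(1.0, abs=1e-6)

    def test_half_overlap_worked_value(self):
        pred = np.full(4, 0.5)
        target = np.array([1.0, 1.0, 0.0, 0.0])
        assert ls.dice_loss(pred, target) == pytest.approx(0.5, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ls.dice_loss(np.zeros(3), np.zeros(4))


class TestCombinedLoss:
    def test_perfect_prediction_is_zero(self):
        target = ls.one_hot(np.array([[[0, 1], [2, 3]]]), 4)
        assert ls.combined_loss(target, target) == pytest.approx(0.0, abs=1e-6)

    def test_zero_dice_weight_reduces_to_focal(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((1, 4, 4, 4))
        probs = ls.softmax(logits, axis=1)
        target = ls.one_hot(rng.integers(0, 4, (1, 4, 4)), 4)
        pt = np.sum(probs * target, axis=1)
        assert ls.combined_loss(probs, target, w_dice=0.0) == pytest.approx(
            ls.focal_loss(pt)
        )

    def test_negative_weight_rejected(self):
        t = ls.one_hot(np.zeros((1, 2, 2), dtype=int), 4)
        with pytest.raises(ValueError):
            ls.combined_loss(t, t, w_focal=-1.0)


class TestLossGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((1, 4, 3, 3))
        labels = rng.integers(0, 4, (1, 3, 3))
        _, grad = ls.segmentation_loss_and_grad(logits, labels)
        eps = 1e-5
        num = np.zeros_like(logits)
        for idx in np.ndindex(logits.shape):
            lp, lm = logits.copy(), logits.copy()
            lp[idx] += eps
            lm[idx] -= eps
            fp, _ = ls.segmentation_loss_and_grad(lp, labels)
            fm, _ = ls.segmentation_loss_and_grad(lm, labels)
            num[idx] = (fp - fm) / (2 * eps)
        assert np.allclose(grad, num, atol=1e-6)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        labels = np.array([0, 0, 1, 2, 3, 3])
        cm = mx.confusion(labels, labels, 4)
        assert np.array_equal(np.diag(cm.counts), [2, 1, 1, 2])
        assert cm.counts.sum() == np.trace(cm.counts)

    def test_hand_tally(self):
        true = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        pred = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        cm = mx.confusion(pred, true, 2)
        assert np.array_equal(cm.counts, [[3, 1], [1, 3]])
        assert cm.total == 8

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            mx.confusion(np.array([0, 4]), np.array([0, 1]), 4)


class TestNormalizeRows:
    def test_hand_division(self):
        cm = mx.ConfusionMatrix(np.array([[3, 1], [1, 3]]), ("a", "b"))
        assert np.allclose(mx.normalize_rows(cm), [[0.75, 0.25], [0.25, 0.75]])

    def test_identity_counts(self):
        cm = mx.ConfusionMatrix(np.eye(3, dtype=int) * 5, ("a", "b", "c"))
        assert np.allclose(mx.normalize_rows(cm), np.eye(3))

    def test_diagonal_equals_recall(self):
        rng = np.random.default_rng(2)
        cm = mx.confusion(rng.integers(0, 4, 500), rng.integers(0, 4, 500), 4)
        normalized = mx.normalize_rows(cm)
        report = mx.metrics_from_confusion(cm)
        assert np.allclose(np.diag(normalized), report.recall)

    def test_zero_row_warns_and_emits_zeros(self):
        cm = mx.ConfusionMatrix(np.array([[4, 0], [0, 0]]), ("a", "b"))
        with pytest.warns(UserWarning, match="no true pixels"):
            out = mx.normalize_rows(cm)
        assert np.allclose(out[1], 0.0)


def brute_force_metrics(pred, true, k):
    """Independent oracle: per-pixel counting loops, no confusion matrix."""
    pred, true = pred.ravel(), true.ravel()
    pa = sum(int(p == t) for p, t in zip(pred, true)) / len(true)
    recalls, ious, f1s = [], [], []
    for c in range(k):
        tp = sum(int(p == c and t == c) for p, t in zip(pred, true))
        fp = sum(int(p == c and t != c) for p, t in zip(pred, true))
        fn = sum(int(p != c and t == c) for p, t in zip(pred, true))
        if tp + fn > 0:
            recalls.append(tp / (tp + fn))
        if tp + fp + fn > 0:
            ious.append(tp / (tp + fp + fn))
            f1s.append(2 * tp / (2 * tp + fp + fn))
    return pa, float(np.mean(recalls)), float(np.mean(ious)), f1s


class TestMetricsFromConfusion:
    def test_perfect_four_class_prediction(self):
        labels = np.tile(np.arange(4), 8)
        report = mx.metrics_from_confusion(mx.confusion(labels, labels, 4))
        assert report.pa == report.mpa == report.miou == 1.0
        assert np.allclose(report.f1, 1.0)

    def test_hand_worked_two_class_case(self):
        cm = mx.ConfusionMatrix(np.array([[3, 1], [1, 3]]), ("a", "b"))
        report = mx.metrics_from_confusion(cm)
        assert report.pa == 0.75
        assert report.iou[0] == pytest.approx(0.6)
        assert report.miou == pytest.approx(0.6)
        assert report.f1[0] == pytest.approx(0.75)

    def test_empty_matrix_rejected(self):
        cm = mx.ConfusionMatrix(np.zeros((3, 3), dtype=int), ("a", "b", "c"))
        with pytest.raises(ValueError):
            mx.metrics_from_confusion(cm)

    def test_oracle_equivalence_on_random_label_maps(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            pred = rng.integers(0, 4, (16, 16))
            true = rng.integers(0, 4, (16, 16))
            report = mx.metrics_from_confusion(mx.confusion(pred, true, 4))
            pa, mpa, miou, f1s = brute_force_metrics(pred, true, 4)
            assert abs(report.pa - pa) <= 1e-12
            assert abs(report.mpa - mpa) <= 1e-12
            assert abs(report.miou - miou) <= 1e-12
            finite_f1 = report.f1[np.isfinite(report.f1)]
            assert np.all(np.abs(finite_f1 - np.array(f1s)) <= 1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        pred = rng.integers(0, 4, 400)
        true = rng.integers(0, 4, 400)
        perm = np.array([2, 0, 3, 1])
        base = mx.metrics_from_confusion(mx.confusion(pred, true, 4))
        permuted = mx.metrics_from_confusion(mx.confusion(perm[pred], perm[true], 4))
        assert permuted.pa == pytest.approx(base.pa)
        assert permuted.mpa == pytest.approx(base.mpa)
        assert permuted.miou == pytest.approx(base.miou)
        inv = np.argsort(perm)
        assert np.allclose(permuted.iou[perm], base.iou)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50)
    )
    def test_f1_equals_harmonic_mean_of_precision_and_recall(self, tp, fp, fn):
        if tp + fp == 0 or tp + fn == 0:
            return
        p = tp / (tp + fp)
        r = tp / (tp + fn)
        f1 = 2 * tp / (2 * tp + fp + fn)
        if p + r > 0:
            assert f1 == pytest.approx(2 * p * r / (p + r))
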