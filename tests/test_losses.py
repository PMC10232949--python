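"""Losses and metrics: oracle equivalence and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra import numpy as hnp

from masunet.autodiff import Tensor
from masunet.losses import (bce_dice_loss, dice_coefficient, evaluate_volume,
                            ppv, sensitivity, soft_dice_loss, softmax_field,
                            weighted_cross_entropy)


class TestSoftmaxField:
    def test_symmetry(self):
        p = softmax_field(np.zeros((2, 3, 3)))
        np.testing.assert_allclose(p, 0.5)

    def test_large_activations_stable(self):
        p = softmax_field(np.array([[[1000.0]], [[0.0]]]))
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p[0], 1.0, atol=1e-12)

    def test_matches_naive_oracle(self, rng):
        a = rng.standard_normal((4, 3, 3))
        expected = np.exp(a) / np.exp(a).sum(axis=0, keepdims=True)
        np.testing.assert_allclose(softmax_field(a), expected, atol=1e-12)

    def test_normalization_invariant(self, rng):
        p = softmax_field(rng.standard_normal((5, 4, 4)) * 10)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-6)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError, match="finite"):
            softmax_field(np.array([[[np.inf]], [[0.0]]]))


class TestWeightedCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        p = np.zeros((2, 2, 2))
        labels = np.array([[1, 2], [2, 1]])
        p[0] = labels == 1
        p[1] = labels == 2
        assert weighted_cross_entropy(p, labels) == 0.0

    def test_uniform_closed_form(self):
        k, n = 4, 9
        p = np.full((k, 3, 3), 1.0 / k)
        labels = np.ones((3, 3), dtype=int)
        np.testing.assert_allclose(weighted_cross_entropy(p, labels),
                                   n * np.log(k), rtol=1e-12)

    def test_matches_pixelwise_hand_sum(self, rng):
        p = softmax_field(rng.standard_normal((2, 2, 2)))
        labels = rng.integers(1, 3, size=(2, 2))
        w = rng.random((2, 2))
        expected = 0.0
        for i in range(2):
            for j in range(2):
                expected -= w[i, j] * np.log(p[labels[i, j] - 1, i, j])
        np.testing.assert_allclose(
            weighted_cross_entropy(p, labels, w), expected, rtol=1e-10)

    def test_zero_probability_clamped_finite(self):
        p = np.zeros((2, 1, 1))
        p[1] = 1.0
        labels = np.ones((1, 1), dtype=int)
        e = weighted_cross_entropy(p, labels)
        assert np.isfinite(e) and e > 0

    def test_minimized_by_one_hot_truth(self, rng):
        """Perturbing p away from the one-hot truth raises the energy."""
        labels = np.array([[1, 2]])
        p_true = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])
        base = weighted_cross_entropy(p_true, labels)
        for eps in (0.01, 0.1, 0.3):
            p = p_true * (1 - eps) + eps / 2
            assert weighted_cross_entropy(p, labels) > base

    def test_bad_labels_raise(self):
        with pytest.raises(ValueError, match="labels"):
            weighted_cross_entropy(np.full((2, 1, 1), 0.5),
                                   np.array([[3]]))


class TestSoftDiceLoss:
    def test_perfect_prediction_zero(self):
        t = np.zeros((2, 4, 4))
        t[0, :2] = 1
        t[1, 2:] = 1
        assert soft_dice_loss(t, t) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_pred_closed_form(self):
        t = np.zeros((1, 4, 4))
        t[0, :2] = 1  # S = 8 true pixels
        s = 1.0
        expected = 1.0 - s / (8 + s)
        assert soft_dice_loss(np.zeros_like(t), t, smooth=s) == \
            pytest.approx(expected, rel=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        p = rng.random((2, 3, 3))
        t = (rng.random((2, 3, 3)) > 0.5).astype(float)
        s = 1.0
        dices = []
        for c in range(2):
            inter = float((p[c] * t[c]).sum())
            dices.append((2 * inter + s) / (p[c].sum() + t[c].sum() + s))
        assert soft_dice_loss(p, t, s) == pytest.approx(
            1.0 - np.mean(dices), rel=1e-12)

    def test_tensor_and_numpy_paths_agree(self, rng):
        p = rng.random((1, 2, 4, 4)).astype(np.float32)
        t = (rng.random((1, 2, 4, 4)) > 0.5).astype(np.float32)
        graph = soft_dice_loss(Tensor(p), Tensor(t)).item()
        plain = soft_dice_loss(p[0], t[0])
        assert graph == pytest.approx(plain, abs=1e-6)

    def test_converges_to_hard_dice_complement(self, rng):
        pred = (rng.random((1, 6, 6)) > 0.5).astype(float)
        true = (rng.random((1, 6, 6)) > 0.5).astype(float)
        loss = soft_dice_loss(pred, true, smooth=1e-9)
        assert loss == pytest.approx(
            1.0 - dice_coefficient(pred[0], true[0]), abs=1e-7)


class TestBceDiceLoss:
    def test_saturated_correct_near_zero(self):
        t = np.zeros((1, 4, 4))
        t[0, :2] = 1
        logits = 20.0 * (2 * t - 1)
        assert bce_dice_loss(logits, t) < 1e-3

    def test_closed_form_at_zero_logits(self):
        n = 16
        t = np.zeros((1, 4, 4))
        expected = np.log(2.0) + (1 - 1.0 / (0.5 * n + 1))
        assert bce_dice_loss(np.zeros_like(t), t, smooth=1.0) == \
            pytest.approx(expected, rel=1e-6)

    def test_ordering_better_logits_lower_loss(self, rng):
        t = (rng.random((2, 5, 5)) > 0.5).astype(float)
        noisy = rng.standard_normal((2, 5, 5))
        assert bce_dice_loss(20.0 * (2 * t - 1), t) < bce_dice_loss(noisy, t)

    def test_tensor_path_matches_numpy(self, rng):
        z = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)
        t = (rng.random((1, 2, 4, 4)) > 0.5).astype(np.float32)
        assert bce_dice_loss(Tensor(z), Tensor(t)).item() == pytest.approx(
            bce_dice_loss(z[0], t[0]), abs=1e-6)


class TestOverlapMetrics:
    def test_worked_count_examples(self):
        pred = np.zeros(10, dtype=bool)
        true = np.zeros(10, dtype=bool)
        pred[:4] = True   # |pred| = 4
        true[2:4] = True  # |true| = 2, overlap 2
        assert dice_coefficient(pred, true) == pytest.approx(2 * 2 / 6)
        assert ppv(pred, true) == pytest.approx(0.5)
        assert sensitivity(pred, true) == pytest.approx(1.0)

    def test_identical_masks_score_one(self, rng):
        m = rng.random((6, 6)) > 0.4
        assert dice_coefficient(m, m) == 1.0
        assert ppv(m, m) == 1.0
        assert sensitivity(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.array([True, True, False, False])
        b = ~a
        assert dice_coefficient(a, b) == 0.0
        assert sensitivity(a, b) == 0.0

    def test_empty_conventions(self):
        empty = np.zeros(4, dtype=bool)
        full = np.ones(4, dtype=bool)
        assert dice_coefficient(empty, empty) == 1.0
        assert ppv(empty, empty) == 1.0
        assert ppv(empty, full) == 0.0
        assert sensitivity(empty, empty) == 1.0
        assert sensitivity(full, empty) == 0.0

    def test_non_binary_raises(self):
        with pytest.raises(ValueError, match="binary"):
            dice_coefficient(np.array([0, 2]), np.array([0, 1]))

    @given(hnp.arrays(bool, (5, 5)), hnp.arrays(bool, (5, 5)))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_metric_range_and_symmetry_property(self, a, b):
        """For arbitrary masks (including empty): metrics stay in [0, 1],
        dice is symmetric, and PPV/sensitivity are dual under swapping."""
        d = dice_coefficient(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice_coefficient(b, a)
        assert 0.0 <= ppv(a, b) <= 1.0
        assert ppv(a, b) == sensitivity(b, a)

    def test_symmetry_duality_harmonic_identities(self):
        """dice symmetry, PPV/sensitivity duality, harmonic-mean identity."""
        gen = np.random.default_rng(99)
        for _ in range(100):
            a = gen.random((8, 8)) > 0.5
            b = gen.random((8, 8)) > 0.5
            a[4, 4] = b[4, 4] = True  # guarantee nonempty overlap
            assert dice_coefficient(a, b) == dice_coefficient(b, a)
            assert ppv(a, b) == sensitivity(b, a)
            h = 2 * ppv(a, b) * sensitivity(a, b) / (
                ppv(a, b) + sensitivity(a, b))
            assert abs(h - dice_coefficient(a, b)) < 1e-12


class TestEvaluateVolume:
    def test_single_slice_equals_slice_metric(self, rng):
        pred = rng.random((2, 5, 5)) > 0.5
        true = rng.random((2, 5, 5)) > 0.5
        rep = evaluate_volume(pred, true)
        assert rep.dice["PZ"] == pytest.approx(
            dice_coefficient(pred[0], true[0]))

    def test_pooled_two_slice_arithmetic(self):
        # slice 1: perfect (dice 1); slice 2: disjoint, equal sizes (dice 0)
        s = np.zeros((2, 4, 4), dtype=bool)
        s[:, 0, :2] = True
        miss = np.zeros_like(s)
        miss[:, 1, :2] = True
        pred = np.stack([s, s], axis=1)
        true = np.stack([s, miss], axis=1)
        rep = evaluate_volume(pred, true)
        assert rep.dice["PZ"] == pytest.approx(0.5)
        assert rep.dice["TZ"] == pytest.approx(0.5)

    def test_all_perfect_volume(self, rng):
        m = rng.random((2, 3, 4, 4)) > 0.5
        rep = evaluate_volume(m, m)
        for name in ("PZ", "TZ"):
            assert rep.dice[name] == rep.ppv[name] == rep.sensitivity[name] == 1.0

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shapes differ"):
            evaluate_volume(np.zeros((2, 2, 4, 4), dtype=bool),
                            np.zeros((2, 3, 4, 4), dtype=bool))
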