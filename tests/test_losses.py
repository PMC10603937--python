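"""Loss functions against independent oracles: hand pixel counts, per-class
decompositions, the level-set (Choquet) integral for the Lovász extension,
and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octostack import (CombinedLossConfig, TverskyParams, binary_dice,
                       combined_loss, lovasz_softmax, multiclass_dice_loss,
                       one_hot, tversky_loss)
from octostack.losses import lovasz_grad
from octostack._tensor import Tensor


def random_probs(rng, C, shape):
    p = rng.dirichlet(np.ones(C), size=shape)
    return np.moveaxis(p, -1, 0)


class TestBinaryDice:
    def test_identical_sets_score_one(self, rng):
        x = (rng.random((5, 5)) > 0.5).astype(float)
        x[0, 0] = 1
        assert binary_dice(x, x, smooth=0) == pytest.approx(1.0)

    def test_disjoint_sets_score_zero(self):
        x = np.zeros((4, 4)); x[0] = 1
        y = np.zeros((4, 4)); y[2] = 1
        assert binary_dice(x, y, smooth=0) == 0.0

    def test_hand_counted_overlap(self):
        # |X| = 4, |Y| = 2, |X ∩ Y| = 1 -> 2*1 / (4+2)
        x = np.zeros((3, 3)); x[0, :3] = 1; x[1, 0] = 1
        y = np.zeros((3, 3)); y[0, 0] = 1; y[2, 2] = 1
        assert binary_dice(x, y, smooth=0) == pytest.approx(2 / 6)

    def test_symmetry_and_shape_check(self, rng):
        x, y = rng.random((4, 4)), rng.random((4, 4))
        assert binary_dice(x, y) == pytest.approx(binary_dice(y, x))
        with pytest.raises(ValueError):
            binary_dice(x, rng.random((4, 5)))

    def test_empty_vs_empty_is_perfect(self):
        z = np.zeros((3, 3))
        assert binary_dice(z, z, smooth=0) == 1.0


class TestMulticlassDice:
    def test_perfect_prediction_zero_loss(self, rng):
        gt = one_hot(rng.integers(0, 3, (6, 6)), 3)
        assert multiclass_dice_loss(gt, gt, smooth=0) == pytest.approx(0.0)

    def test_equals_mean_of_per_class_binary_losses(self, rng):
        C = 3
        gt = one_hot(rng.integers(0, C, (4, 4)), C)
        P = random_probs(rng, C, (4, 4))
        expected = np.mean([1 - binary_dice(gt[c], P[c]) for c in range(C)])
        assert multiclass_dice_loss(gt, P) == pytest.approx(expected, abs=1e-12)

    def test_class_count_mismatch_rejected(self, rng):
        gt = one_hot(rng.integers(0, 2, (4, 4)), 2)
        with pytest.raises(ValueError):
            multiclass_dice_loss(gt, random_probs(rng, 3, (4, 4)))


class TestLovasz:
    def test_perfect_prediction_zero_loss(self, rng):
        mask = rng.integers(0, 3, (5, 5))
        assert lovasz_softmax(mask, one_hot(mask, 3)) == pytest.approx(0.0)

    def test_hard_onehot_prediction_equals_one_minus_iou(self, rng):
        for _ in range(50):
            C = int(rng.integers(2, 5))
            gt = rng.integers(0, C, (6, 6))
            pred = rng.integers(0, C, (6, 6))
            vals = []
            for c in np.unique(gt):
                inter = ((gt == c) & (pred == c)).sum()
                union = ((gt == c) | (pred == c)).sum()
                vals.append(1 - inter / union if union else 0.0)
            got = lovasz_softmax(gt, one_hot(pred, C), "present")
            assert got == pytest.approx(np.mean(vals), abs=1e-12)

    def test_matches_level_set_choquet_integral(self, rng):
        """On <=8 pixels with one foreground class the loss equals
        ∫₀¹ J({i : error_i >= t}) dt computed on a dense t-grid."""
        for _ in range(20):
            n = int(rng.integers(2, 9))
            fg = rng.integers(0, 2, n).astype(float)
            if fg.sum() == 0:
                fg[0] = 1.0
            p = rng.random(n)
            errors = np.abs(fg - p)
            perm = np.argsort(-errors, kind="stable")
            mine = float((errors[perm] * lovasz_grad(fg[perm])).sum())
            ts = np.linspace(0, 1, 10_000)
            total = fg.sum()
            vals = []
            for t in ts:
                S = errors >= t
                if not S.any():
                    vals.append(0.0)
                    continue
                inter = total - fg[S].sum()
                union = total + (1 - fg)[S].sum()
                vals.append(1 - inter / union)
            oracle = np.trapezoid(vals, ts)
            assert mine == pytest.approx(oracle, abs=1e-3)

    def test_piecewise_linear_convex_along_random_directions(self, rng):
        """Midpoint check of convexity in prediction space (n <= 8)."""
        n = 6
        fg = np.array([1, 0, 1, 1, 0, 0], float)
        mask = fg.reshape(2, 3).astype(int)

        def loss_at(p):
            P = np.stack([1 - p, p]).reshape(2, 2, 3)
            return lovasz_softmax(mask, P, "present")

        for _ in range(30):
            a, b = rng.random(n), rng.random(n)
            mid = 0.5 * (a + b)
            assert loss_at(mid) <= 0.5 * (loss_at(a) + loss_at(b)) + 1e-9

    def test_empty_ground_truth_with_present_mode_rejected(self):
        P = random_probs(np.random.default_rng(0), 3, (2, 2))
        with pytest.raises(ValueError):
            lovasz_softmax(np.zeros((0, 0), int), P, "present")


class TestTversky:
    def test_reduces_to_dice_at_half_half(self, rng):
        for _ in range(100):
            C = 3
            gt = one_hot(rng.integers(0, C, (4, 4)), C)
            P = random_probs(rng, C, (4, 4))
            d = multiclass_dice_loss(gt, P, smooth=0)
            t = tversky_loss(gt, P, TverskyParams(0.5, 0.5), smooth=0)
            assert t == pytest.approx(d, abs=1e-9)

    def test_hand_evaluated_hard_sets(self):
        # one class with |X∩Y|=1, |X−Y|=3, |Y−X|=1 at alpha=beta=0.5:
        # 1 - 1/(1 + 0.5*3 + 0.5*1) = 2/3
        gt = np.zeros((1, 2, 4)); gt[0, 0] = 1                  # |X| = 4
        pred = np.zeros((1, 2, 4)); pred[0, 0, 0] = 1; pred[0, 1, 0] = 1
        loss = tversky_loss(gt, pred, TverskyParams(0.5, 0.5), smooth=0)
        assert loss == pytest.approx(2 / 3)

    def test_perfect_prediction_zero_loss(self, rng):
        gt = one_hot(rng.integers(0, 3, (5, 5)), 3)
        assert tversky_loss(gt, gt) == pytest.approx(0.0, abs=1e-5)

    def test_monotone_in_alpha_when_false_negatives_exist(self, rng):
        gt = one_hot(rng.integers(0, 2, (5, 5)), 2)
        P = random_probs(rng, 2, (5, 5))
        losses = [tversky_loss(gt, P, TverskyParams(a, 0.5))
                  for a in (0.1, 0.5, 1.0, 2.0)]
        assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            TverskyParams(0.0, 0.0)


class TestCombined:
    def test_weighted_sum_of_components(self, rng):
        C = 3
        mask = rng.integers(0, C, (6, 6))
        P = random_probs(rng, C, (6, 6))
        cfg = CombinedLossConfig()
        expected = (0.5 * multiclass_dice_loss(one_hot(mask, C), P,
                                               smooth=cfg.smooth)
                    + 0.3 * lovasz_softmax(mask, P)
                    + 0.2 * tversky_loss(one_hot(mask, C), P,
                                         smooth=cfg.smooth))
        assert combined_loss(mask, P, cfg) == pytest.approx(expected, abs=1e-12)

    def test_fixed_weight_arithmetic(self):
        # component values (1, 0, 0.5) under weights (0.5, 0.3, 0.2)
        assert 0.5 * 1 + 0.3 * 0 + 0.2 * 0.5 == pytest.approx(0.6)

    def test_perfect_prediction_zero_loss(self, rng):
        mask = rng.integers(0, 3, (4, 4))
        assert combined_loss(mask, one_hot(mask, 3)) == pytest.approx(0.0, abs=1e-5)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            CombinedLossConfig(w_dice=-0.1)


class TestGradientsAndRobustness:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_losses_finite_on_fuzzed_inputs(self, seed):
        """No NaN/inf on random inputs, including all-background masks."""
        g = np.random.default_rng(seed)
        C = int(g.integers(2, 5))
        mask = g.integers(0, C, (4, 4)) if seed % 3 else np.zeros((4, 4), int)
        P = random_probs(g, C, (4, 4))
        for val in (multiclass_dice_loss(one_hot(mask, C), P),
                    lovasz_softmax(mask, P),
                    tversky_loss(one_hot(mask, C), P),
                    combined_loss(mask, P)):
            assert np.isfinite(val)

    def test_all_losses_differentiable_with_finite_gradients(self, rng):
        C = 3
        mask = rng.integers(0, C, (4, 4))
        logits = Tensor(rng.normal(size=(C, 4, 4)), requires_grad=True)
        from octostack._tensor import softmax
        P = softmax(logits, axis=0)
        loss = combined_loss(mask, P)
        loss.backward()
        assert np.isfinite(logits.grad).all()
        assert np.abs(logits.grad).sum() > 0

    def test_hard_imperfect_prediction_strictly_positive(self, rng):
        mask = rng.integers(0, 3, (4, 4))
        pred = mask.copy()
        pred[0, 0] = (pred[0, 0] + 1) % 3
        assert combined_loss(mask, one_hot(pred, 3),
                             CombinedLossConfig(smooth=0)) > 0
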