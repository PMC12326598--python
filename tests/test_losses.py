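"""Unit and oracle tests for the weighted-focal-loss family."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxembed.labels import SparseLabelMatrix
from toxembed.losses import (
    ClasswiseLoss,
    LossConfig,
    bce_loss,
    classwise_logloss,
    masking_loss,
    physchem_loss,
    positive_weights,
    weighted_focal_loss,
)


def _random_problem(rng, n=10, p=5, missing=0.3):
    y = rng.integers(0, 2, size=(n, p)).astype(float)
    y[rng.random((n, p)) < missing] = np.nan
    # ensure at least one observed entry
    y[0, 0] = 1.0
    f = rng.normal(scale=2.0, size=(n, p))
    return y, f


def loop_focal_loss(y, f, alpha, gamma, reduction="mean"):
    """Scalar double-loop reference for the weighted focal loss."""

    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    n, p = y.shape
    w = np.ones(p)
    for j in range(p):
        obs = [i for i in range(n) if not np.isnan(y[i, j])]
        npos = sum(y[i, j] == 1 for i in obs)
        nneg = len(obs) - npos
        if npos > 0:
            w[j] = alpha * nneg / npos + (1 - alpha)
    total, count = 0.0, 0
    for i in range(n):
        for j in range(p):
            if np.isnan(y[i, j]):
                continue
            s = sig(f[i, j])
            if y[i, j] == 1:
                total += w[j] * (1 - s) ** gamma * (-np.log(s))
            else:
                total += s**gamma * (-np.log(1 - s))
            count += 1
    return total / count if reduction == "mean" else total


def loop_classwise(y, f):
    """Scalar reference for the per-class log-loss."""

    def sig(x):
        return 1.0 / (1.0 + np.exp(-x))

    n, p = y.shape
    lpos, lneg = np.full(p, np.nan), np.full(p, np.nan)
    for j in range(p):
        pos = [-np.log(sig(f[i, j])) for i in range(n) if y[i, j] == 1]
        neg = [-np.log(1 - sig(f[i, j])) for i in range(n) if y[i, j] == 0]
        if pos:
            lpos[j] = np.mean(pos)
        if neg:
            lneg[j] = np.mean(neg)
    return lpos, lneg


class TestPositiveWeights:
    def test_inverse_ratio_at_full_balancing(self):
        assert positive_weights([10], [90], alpha=1.0)[0] == pytest.approx(9.0)

    def test_unweighted_at_alpha_zero(self):
        assert positive_weights([3], [97], alpha=0.0)[0] == pytest.approx(1.0)

    def test_interpolates(self):
        # N-/N+ = 9, alpha = 0.5 -> 0.5*9 + 0.5 = 5
        assert positive_weights([10], [90], alpha=0.5)[0] == pytest.approx(5.0)

    def test_no_positives_warns_and_is_nan(self):
        with pytest.warns(UserWarning):
            w = positive_weights([0, 5], [10, 10], alpha=1.0)
        assert np.isnan(w[0]) and w[1] == pytest.approx(2.0)

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            positive_weights([1], [1], alpha=1.5)


class TestWeightedFocalLoss:
    def test_bce_at_origin_of_family(self):
        # y=1, f=0 -> ln 2 per entry
        y = np.ones((1, 1))
        f = np.zeros((1, 1))
        assert bce_loss(y, f) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_scalar_evaluation_with_focusing(self):
        # w+=3, gamma=2, y=1, sigma(f)=0.9 -> 3 * 0.01 * (-ln 0.9)
        f = np.array([[np.log(0.9 / 0.1)]])
        y = np.ones((1, 1))
        cfg = LossConfig(gamma=2.0, weights=np.array([3.0]))
        expected = 3.0 * 0.1**2 * (-np.log(0.9))
        assert weighted_focal_loss(y, f, cfg) == pytest.approx(expected, rel=1e-10)

    def test_perfect_prediction_vanishes(self):
        y = np.ones((1, 1))
        f = np.array([[40.0]])
        assert weighted_focal_loss(y, f, LossConfig(gamma=2.0)) < 1e-15

    def test_reduction_identities_on_random_instances(self, rng):
        """FLw collapses to BCE / weighted BCE / FL at the stated corners."""
        for _ in range(50):
            y, f = _random_problem(rng)
            base = weighted_focal_loss(y, f, LossConfig(0.0, 0.0))
            assert base == pytest.approx(loop_focal_loss(y, f, 0.0, 0.0), abs=1e-10)
            for alpha, gamma in [(0.0, 0.0), (1.0, 0.0), (0.0, 2.0), (0.7, 1.5)]:
                got = weighted_focal_loss(y, f, LossConfig(alpha, gamma))
                want = loop_focal_loss(y, f, alpha, gamma)
                assert got == pytest.approx(want, abs=1e-10)

    def test_sum_reduction_matches_double_sum(self, rng):
        y, f = _random_problem(rng)
        got = weighted_focal_loss(y, f, LossConfig(1.0, 2.0, reduction="sum"))
        assert got == pytest.approx(loop_focal_loss(y, f, 1.0, 2.0, "sum"), abs=1e-10)

    def test_alpha_monotone_in_positive_contribution(self, rng):
        """On imbalanced tasks (negatives outnumber positives), more
        balancing never lowers the loss put on positives (sum reduction
        isolates the positive terms)."""
        y = np.zeros((10, 5))
        y[:2] = 1.0  # 2 positives, 8 negatives per task
        f = rng.normal(scale=2.0, size=y.shape)
        values = [
            weighted_focal_loss(y, f, LossConfig(alpha, 1.0, "sum"))
            for alpha in np.linspace(0, 1, 6)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_focal_term_shrinks_correct_entries(self):
        """gamma > 0 strictly reduces the per-entry loss whenever the
        entry is classified on the correct side."""
        y = np.array([[1.0, 0.0]])
        f = np.array([[1.3, -0.7]])  # both correct
        plain = weighted_focal_loss(y, f, LossConfig(0.0, 0.0))
        focused = weighted_focal_loss(y, f, LossConfig(0.0, 2.0))
        assert focused < plain

    def test_missing_entries_are_skipped(self):
        y = np.array([[1.0, np.nan]])
        f = np.array([[0.0, 50.0]])
        assert weighted_focal_loss(y, f, LossConfig()) == pytest.approx(np.log(2.0))

    def test_errors(self):
        with pytest.raises(ValueError):
            weighted_focal_loss(np.array([[np.nan]]), np.zeros((1, 1)), LossConfig())
        with pytest.raises(ValueError):
            weighted_focal_loss(np.ones((1, 1)), np.array([[np.nan]]), LossConfig())

    def test_accepts_sparse_label_matrix(self):
        m = SparseLabelMatrix(np.array([[1.0, 0.0]]), ["a", "b"])
        assert weighted_focal_loss(m, np.zeros((1, 2)), LossConfig()) == pytest.approx(
            np.log(2.0)
        )

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_vectorized_equals_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        y, f = _random_problem(rng)
        alpha = float(rng.uniform(0, 1))
        gamma = float(rng.uniform(0, 3))
        got = weighted_focal_loss(y, f, LossConfig(alpha, gamma))
        assert got == pytest.approx(loop_focal_loss(y, f, alpha, gamma), abs=1e-10)


class TestMaskingLoss:
    def test_uniform_logits_give_log_vocab(self):
        v = 17
        logits = np.zeros((1, 3, v))
        tokens = np.array([[1, 2, 3]])
        mask = np.array([[False, True, False]])
        assert masking_loss(logits, tokens, mask) == pytest.approx(np.log(v))

    def test_confident_correct_prediction_vanishes(self):
        logits = np.zeros((1, 2, 5))
        logits[0, 0, 3] = 60.0
        tokens = np.array([[3, 1]])
        mask = np.array([[True, False]])
        assert masking_loss(logits, tokens, mask) < 1e-12

    def test_unmasked_positions_contribute_nothing(self, rng):
        logits = rng.normal(size=(2, 4, 6))
        tokens = rng.integers(0, 6, size=(2, 4))
        mask = np.zeros((2, 4), dtype=bool)
        mask[0, 1] = True
        only = masking_loss(logits, tokens, mask)
        logits[1] = 1e3 * rng.normal(size=(4, 6))  # perturb unmasked rows
        assert masking_loss(logits, tokens, mask) == pytest.approx(only)

    def test_zero_masked_positions_error(self):
        with pytest.raises(ValueError):
            masking_loss(np.zeros((1, 2, 4)), np.zeros((1, 2), int), np.zeros((1, 2), bool))


class TestPhyschemLoss:
    def test_identity_is_zero(self, rng):
        x = rng.normal(size=(4, 7))
        assert physchem_loss(x, x) == 0.0

    def test_single_sample_squared_norm(self):
        assert physchem_loss(np.array([[2.0]]), np.array([[0.0]])) == pytest.approx(4.0)

    def test_mean_over_samples(self):
        est = np.array([[2.0, 0.0], [1.0, 1.0]])
        tgt = np.array([[0.0, 0.0], [0.0, 3.0]])  # squared norms 4 and 5
        assert physchem_loss(est, tgt) == pytest.approx(4.5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            physchem_loss(np.zeros((2, 3)), np.zeros((2, 4)))


class TestClasswiseLogloss:
    def test_symmetric_point(self):
        y = np.array([[1.0], [0.0]])
        f = np.zeros((2, 1))
        cw = classwise_logloss(y, f)
        assert cw.loss_pos[0] == pytest.approx(np.log(2.0))
        assert cw.loss_neg[0] == pytest.approx(np.log(2.0))

    def test_calibrated_confident(self):
        p = 0.9
        f = np.array([[np.log(p / (1 - p))], [np.log((1 - p) / p)]])
        y = np.array([[1.0], [0.0]])
        cw = classwise_logloss(y, f)
        assert cw.loss_pos[0] == pytest.approx(-np.log(0.9), rel=1e-9)
        assert cw.loss_neg[0] == pytest.approx(-np.log(0.9), rel=1e-9)

    def test_confident_wrong_positives_blow_up(self):
        p = 0.01
        f = np.array([[np.log(p / (1 - p))], [np.log(p / (1 - p))]])
        y = np.array([[1.0], [0.0]])
        cw = classwise_logloss(y, f)
        assert cw.loss_pos[0] == pytest.approx(-np.log(0.01), rel=1e-6)
        assert cw.loss_pos[0] > 40 * cw.loss_neg[0]

    def test_single_class_side_undefined(self):
        y = np.array([[1.0], [1.0]])
        cw = classwise_logloss(y, np.zeros((2, 1)))
        assert np.isnan(cw.loss_neg[0]) and not np.isnan(cw.loss_pos[0])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        y, f = _random_problem(rng)
        cw = classwise_logloss(y, f)
        lpos, lneg = loop_classwise(y, f)
        np.testing.assert_allclose(cw.loss_pos, lpos, atol=1e-10, equal_nan=True)
        np.testing.assert_allclose(cw.loss_neg, lneg, atol=1e-10, equal_nan=True)
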