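"""Loss values against per-pixel hand arithmetic, gradients against finite differences."""

import numpy as np
import pytest

from swsal.losses import (
    DICE_EPS,
    JointSchedule,
    area_loss,
    area_loss_grad,
    joint_loss,
    schedule_weights,
    weighted_edge_loss,
    weighted_edge_loss_grad,
)


def _area_loss_bruteforce(label, pred):
    """Independent per-pixel arithmetic for BCE mean + smoothed Dice loss."""
    qc = np.clip(pred, 1e-7, 1 - 1e-7)
    bce = 0.0
    inter = s_label = s_pred = 0.0
    for g, qq, qcc in zip(label.ravel(), pred.ravel(), qc.ravel()):
        bce += -(g * np.log(qcc) + (1 - g) * np.log(1 - qcc))
        inter += g * qq
        s_label += g
        s_pred += qq
    bce /= label.size
    return bce + 1 - (2 * inter + DICE_EPS) / (s_label + s_pred + DICE_EPS)


class TestAreaLoss:
    def test_perfect_prediction_near_zero(self):
        label = np.zeros((4, 4))
        label[1:3, 1:3] = 1
        assert area_loss(label, label.astype(float)) < 1e-5

    def test_empty_label_empty_pred(self):
        z = np.zeros((4, 4))
        assert area_loss(z, z) < 1e-5

    def test_two_by_two_hand_case(self):
        label = np.array([[1.0, 0.0], [0.0, 0.0]])
        pred = np.array([[0.8, 0.2], [0.2, 0.2]])
        assert area_loss(label, pred) == pytest.approx(_area_loss_bruteforce(label, pred), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_cases_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        label = (rng.random((5, 5)) > 0.5).astype(float)
        pred = rng.random((5, 5))
        assert area_loss(label, pred) == pytest.approx(_area_loss_bruteforce(label, pred), abs=1e-9)

    def test_minimized_at_label(self):
        # gradient vanishes (up to clipping effects) at pred == label
        label = np.zeros((3, 3))
        label[1, 1] = 1
        g = area_loss_grad(label, label.astype(float))
        # interior of the clip: gradient pushes nowhere to improve
        rng = np.random.default_rng(0)
        base = area_loss(label, label.astype(float))
        for _ in range(5):
            other = np.clip(label + rng.normal(0, 0.05, label.shape), 0, 1)
            assert area_loss(label, other) >= base

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            area_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestWeightedEdgeLoss:
    def test_all_edge_label_perfect_pred(self):
        e = np.ones((4, 4))
        # w0 = 1, w1 = 0 and a perfect prediction gives ~0
        assert weighted_edge_loss(e, np.ones((4, 4))) < 1e-5

    def test_empty_edge_label_uses_background_term_only(self):
        e = np.zeros((4, 4))
        pred = np.full((4, 4), 0.3)
        # w0 = 0: only the background term -w1*log(1-s) remains
        expected = -np.log(0.7)
        assert weighted_edge_loss(e, pred) == pytest.approx(expected, rel=1e-9)

    def test_ten_by_ten_hand_case(self):
        rng = np.random.default_rng(3)
        e = np.zeros((10, 10))
        e[0, :8] = 1  # 8 edge pixels -> w0 = 0.08, w1 = 0.92
        s = np.clip(rng.random((10, 10)), 1e-7, 1 - 1e-7)
        acc = 0.0
        for ev, sv in zip(e.ravel(), s.ravel()):
            acc += -(0.08 * ev * np.log(sv) + 0.92 * (1 - ev) * np.log(1 - sv))
        assert weighted_edge_loss(e, s) == pytest.approx(acc / 100, abs=1e-9)

    def test_swap_exchanges_weights(self):
        e = np.zeros((5, 5))
        e[2, 2] = 1
        pred = np.full((5, 5), 0.4)
        w0 = 1 / 25
        direct = -(w0 * np.log(0.4) + (1 - w0) * 24 * np.log(0.6)) / 25
        swapped = -((1 - w0) * np.log(0.4) + w0 * 24 * np.log(0.6)) / 25
        assert weighted_edge_loss(e, pred) == pytest.approx(direct, rel=1e-9)
        assert weighted_edge_loss(e, pred, edge_weight_swap=True) == pytest.approx(swapped, rel=1e-9)


class TestGradients:
    @pytest.mark.parametrize("grad_fn, loss_fn", [
        (area_loss_grad, area_loss),
        (weighted_edge_loss_grad, weighted_edge_loss),
    ])
    def test_matches_finite_differences(self, grad_fn, loss_fn):
        rng = np.random.default_rng(0)
        label = (rng.random((6, 6)) > 0.7).astype(float)
        pred = np.clip(rng.random((6, 6)), 0.05, 0.95)
        analytic = grad_fn(label, pred)
        eps = 1e-7
        for idx in [(0, 0), (2, 3), (5, 5)]:
            up = pred.copy(); up[idx] += eps
            dn = pred.copy(); dn[idx] -= eps
            fd = (loss_fn(label, up) - loss_fn(label, dn)) / (2 * eps)
            assert analytic[idx] == pytest.approx(fd, rel=1e-4)


class TestSchedule:
    @pytest.mark.parametrize("e_cur, expected", [
        (0, (1.0, 0.0)),
        (10, (0.0, 1.0)),
        (5, (0.5, 0.5)),
        (15, (0.0, 1.0)),  # past the threshold: stays pure true-label
    ])
    def test_weight_endpoints_and_linearity(self, e_cur, expected):
        s = JointSchedule(e_thres=10, e_total=20, e_cur=e_cur)
        assert schedule_weights(s) == pytest.approx(expected)

    def test_weights_sum_to_one_until_threshold(self):
        for e_cur in range(11):
            a, b = schedule_weights(JointSchedule(e_thres=10, e_total=20, e_cur=e_cur))
            assert a + b == pytest.approx(1.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            JointSchedule(e_thres=0, e_total=10)
        with pytest.raises(ValueError):
            JointSchedule(e_thres=5, e_total=10, e_cur=-1)


class TestJointLoss:
    def test_endpoint_reduction(self):
        end = JointSchedule(e_thres=4, e_total=8, e_cur=4)
        assert joint_loss(9.0, 9.0, 1.5, 0.5, end) == pytest.approx(2.0)
        start = JointSchedule(e_thres=4, e_total=8, e_cur=0)
        assert joint_loss(1.0, 0.25, 9.0, 9.0, start) == pytest.approx(1.25)

    def test_midpoint_hand_arithmetic(self):
        mid = JointSchedule(e_thres=4, e_total=8, e_cur=2)
        # 0.5*(1.0+0.5) + 0.5*(2.0+0.25)
        assert joint_loss(1.0, 0.5, 2.0, 0.25, mid) == pytest.approx(1.875)

    def test_piecewise_linear_in_round(self):
        vals = [
            joint_loss(1.0, 1.0, 3.0, 3.0, JointSchedule(e_thres=10, e_total=30, e_cur=e))
            for e in range(21)
        ]
        diffs = np.diff(vals[:11])
        assert np.allclose(diffs, diffs[0])  # linear up to the threshold
        assert np.allclose(vals[10:], vals[10])  # constant beyond
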