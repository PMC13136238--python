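"""Loss terms: closed forms, sign structure, gradient directions, assembly."""

import numpy as np
import pytest

from espdnet.losses import (LossConfig, anneal_weight, boundary_loss,
                            dice_loss, edl_loss, focal_loss, liver_loss,
                            signed_distance_map, total_loss)
from espdnet.nn import Tensor


class TestDice:
    def test_perfect_overlap_is_zero(self):
        t = np.zeros((8, 8))
        t[2:5, 2:5] = 1
        assert float(dice_loss(Tensor(t), t).data) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_masses_with_unit_epsilon(self):
        pred = np.zeros((20, 20))
        target = np.zeros((20, 20))
        pred[:5, :20] = 1        # area 100
        target[10:15, :20] = 1   # area 100, disjoint
        val = float(dice_loss(Tensor(pred), target).data)
        assert val == pytest.approx(1.0 - 1.0 / 201.0, abs=1e-6)

    def test_half_overlap_in_epsilon_free_limit(self):
        target = np.zeros((4, 4))
        target[0, :4] = 1                      # 4 target pixels
        pred = np.zeros((4, 4))
        pred[0, :2] = 1                        # covers half...
        pred[1, :2] = 1                        # ...plus 2 false positives
        val = float(dice_loss(Tensor(pred), target, eps=1e-12).data)
        assert val == pytest.approx(0.5, abs=1e-6)

    def test_bounded_below_one(self, rng):
        p = rng.uniform(0, 1, (8, 8))
        t = (rng.uniform(0, 1, (8, 8)) < 0.2).astype(float)
        assert 0.0 <= float(dice_loss(Tensor(p), t).data) < 1.0


class TestFocal:
    def test_confident_correct_is_near_zero(self):
        t = np.ones((2, 2))
        val = float(focal_loss(Tensor(np.ones((2, 2))), t).data)
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_closed_form_at_half(self):
        t = np.ones((1, 1))
        val = float(focal_loss(Tensor(np.full((1, 1), 0.5)), t,
                               gamma=2.0, alpha_f=0.25).data)
        assert val == pytest.approx(0.25 * 0.25 * np.log(2.0), abs=1e-6)

    def test_gamma_zero_reduces_to_weighted_cross_entropy(self, rng):
        p = rng.uniform(0.1, 0.9, (6, 6))
        t = (rng.uniform(0, 1, (6, 6)) < 0.3).astype(float)
        val = float(focal_loss(Tensor(p), t, gamma=0.0, alpha_f=0.5).data)
        bce = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
        assert val == pytest.approx(0.5 * bce, abs=1e-5)


class TestBoundary:
    def test_signed_distance_sign_structure(self):
        t = np.zeros((9, 9))
        t[2:7, 2:7] = 1
        phi = signed_distance_map(t)
        assert phi[4, 4] < 0            # deep interior
        assert phi[2, 2] == 0           # contour pixel
        assert phi[0, 0] > 0            # outside

    def test_zero_prediction_is_zero(self):
        t = np.zeros((5, 5))
        t[1:4, 1:4] = 1
        assert float(boundary_loss(Tensor(np.zeros((5, 5))), t).data) == 0.0

    def test_matching_indicator_is_strictly_negative(self):
        t = np.zeros((9, 9))
        t[2:7, 2:7] = 1
        assert float(boundary_loss(Tensor(t.copy()), t).data) < 0

    def test_complement_indicator_is_strictly_positive(self):
        t = np.zeros((9, 9))
        t[2:7, 2:7] = 1
        assert float(boundary_loss(Tensor(1.0 - t), t).data) > 0

    def test_empty_target_degenerate_rule(self):
        pred = np.full((3, 4), 0.5)
        val = float(boundary_loss(Tensor(pred), np.zeros((3, 4))).data)
        assert val == pytest.approx(0.5 * float(np.hypot(3, 4)), abs=1e-6)

    def test_normalized_form_is_scale_free(self):
        t = np.zeros((9, 9))
        t[2:7, 2:7] = 1
        raw = float(boundary_loss(Tensor(1.0 - t), t).data)
        norm = float(boundary_loss(Tensor(1.0 - t), t, normalize=True).data)
        assert norm == pytest.approx(raw / float(np.hypot(9, 9)), abs=1e-6)


class TestLiver:
    def test_weight_selection(self):
        d, f, b = Tensor(np.asarray(0.3)), Tensor(np.asarray(0.7)), Tensor(np.asarray(-0.1))
        only_dice = liver_loss(d, f, b, LossConfig(alpha_w=1, beta_w=0, gamma_w=0))
        assert float(only_dice.data) == pytest.approx(0.3)
        zero = liver_loss(d, f, b, LossConfig(alpha_w=0, beta_w=0, gamma_w=0))
        assert float(zero.data) == 0.0

    def test_weighted_sum_arithmetic(self):
        d, f, b = Tensor(np.asarray(0.2)), Tensor(np.asarray(0.04)), Tensor(np.asarray(-0.1))
        val = liver_loss(d, f, b, LossConfig(alpha_w=1, beta_w=1, gamma_w=0.5))
        assert float(val.data) == pytest.approx(0.19, abs=1e-7)


class TestEDL:
    @pytest.mark.parametrize("alpha,expected", [
        ([1.0, 1.0], 1.0),       # psi(2) - psi(1)
        ([2.0, 1.0], 0.5),       # psi(3) - psi(2)
        ([10.0, 1.0], 0.1),      # psi(11) - psi(10)
    ])
    def test_digamma_closed_forms(self, alpha, expected):
        a = np.array(alpha).reshape(2, 1, 1)
        y = np.array([1.0, 0.0]).reshape(2, 1, 1)
        val = float(edl_loss(Tensor(a[None]), y[None], axis=1).data)
        assert val == pytest.approx(expected, abs=1e-6)

    def test_nonnegative_everywhere(self, rng):
        a = 1.0 + rng.gamma(2.0, 3.0, size=(2, 2, 5, 5))
        t = (rng.uniform(0, 1, (2, 5, 5)) < 0.5).astype(float)
        y = np.stack([1 - t, t], axis=1)
        assert float(edl_loss(Tensor(a), y, axis=1).data) >= 0.0

    def test_gradient_rewards_true_class_evidence(self):
        """Finite differences: more true-class evidence lowers the loss,
        more wrong-class evidence raises it."""
        y = np.array([[[[1.0]], [[0.0]]]])
        a = np.array([[[[3.0]], [[2.0]]]])
        base = float(edl_loss(Tensor(a), y).data)
        up_true = a.copy(); up_true[0, 0] += 0.1
        up_wrong = a.copy(); up_wrong[0, 1] += 0.1
        assert float(edl_loss(Tensor(up_true), y).data) < base
        assert float(edl_loss(Tensor(up_wrong), y).data) > base

    def test_analytic_gradient_matches_finite_difference(self):
        y = np.array([[[[1.0]], [[0.0]]]])
        a = Tensor(np.array([[[[3.0]], [[2.0]]]]), requires_grad=True)
        edl_loss(a, y).backward()
        eps = 1e-5
        for k in range(2):
            ap = a.data.copy(); ap[0, k] += eps
            am = a.data.copy(); am[0, k] -= eps
            fd = (float(edl_loss(Tensor(ap), y).data)
                  - float(edl_loss(Tensor(am), y).data)) / (2 * eps)
            assert a.grad[0, k, 0, 0] == pytest.approx(fd, abs=1e-5)

    def test_alpha_below_one_rejected(self):
        with pytest.raises(ValueError):
            edl_loss(Tensor(np.array([[[[0.5]], [[1.5]]]])),
                     np.array([[[[1.0]], [[0.0]]]]))


class TestTotal:
    def test_anneal_schedule(self):
        assert anneal_weight(0, 10) == 0.0
        assert anneal_weight(5, 10) == 0.5
        assert anneal_weight(10, 10) == 1.0
        assert anneal_weight(25, 10) == 1.0

    def test_total_at_anneal_endpoints(self):
        cfg = LossConfig(edl_weight=1.0, edl_anneal_epochs=10)
        liver = Tensor(np.asarray(0.4))
        edl = Tensor(np.asarray(0.3))
        assert float(total_loss(liver, edl, 0, cfg).data) == pytest.approx(0.4)
        assert float(total_loss(liver, edl, 10, cfg).data) == pytest.approx(0.7)
        assert float(total_loss(liver, edl, 5, cfg).data) == pytest.approx(0.55)
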