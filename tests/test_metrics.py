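"""Metrics: confusion counts, surface distances vs brute force, calibration,
permutation inference."""

import numpy as np
import pytest

from espdnet.metrics import (boundary_f1,
                             expected_calibration_error,
                             paired_permutation_test, region_metrics,
                             surface_distances,
                             uncertainty_error_correlation)


def brute_force_surface(pred, target):
    """Independent oracle: boundary pixels by explicit neighbour scan,
    all-pairs Euclidean distances, pooled percentile/mean."""
    def boundary(m):
        # mask pixel with a background 8-neighbour inside the image
        m = m.astype(bool)
        pts = []
        H, W = m.shape
        for i in range(H):
            for j in range(W):
                if not m[i, j]:
                    continue
                edge = False
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if 0 <= ni < H and 0 <= nj < W and not m[ni, nj]:
                            edge = True
                if edge:
                    pts.append((i, j))
        if not pts:                       # no interior contour: border ring
            for i in range(H):
                for j in range(W):
                    if m[i, j] and (i in (0, H - 1) or j in (0, W - 1)):
                        pts.append((i, j))
        if not pts:
            pts = [tuple(p) for p in np.argwhere(m)]
        return np.array(pts, dtype=float)

    bp, bt = boundary(pred), boundary(target)
    d = np.sqrt(((bp[:, None, :] - bt[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, 95)), float(pooled.mean())


class TestRegionMetrics:
    def test_perfect_prediction(self):
        t = np.zeros((6, 6), bool)
        t[1:4, 1:4] = True
        assert region_metrics(t, t) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_nonempty(self):
        a = np.zeros((6, 6), bool); a[0, 0] = True
        b = np.zeros((6, 6), bool); b[5, 5] = True
        assert region_metrics(a, b) == (0.0, 0.0, 0.0, 0.0)

    def test_confusion_count_arithmetic(self):
        pred = np.zeros((4, 4), bool)
        target = np.zeros((4, 4), bool)
        pred[0, :4] = True               # 4 predicted
        target[0, 2:] = True             # TP = 2, FP = 2
        target[1, :2] = True             # FN = 2
        dice, iou, prec, sens = region_metrics(pred, target)
        assert dice == pytest.approx(0.5)
        assert iou == pytest.approx(1.0 / 3.0)
        assert prec == pytest.approx(0.5)
        assert sens == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), bool)
        assert region_metrics(z, z) == (1.0, 1.0, 1.0, 1.0)


class TestSurfaceDistances:
    def test_identical_masks_are_zero(self):
        t = np.zeros((8, 8), bool)
        t[2:6, 2:6] = True
        assert surface_distances(t, t) == (0.0, 0.0)

    def test_three_four_five_offset(self):
        a = np.zeros((10, 10), bool); a[1, 1] = True
        b = np.zeros((10, 10), bool); b[4, 5] = True
        hd95, assd = surface_distances(a, b)
        assert hd95 == pytest.approx(5.0)
        assert assd == pytest.approx(5.0)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            size = int(rng.integers(8, 33))
            pred = rng.uniform(0, 1, (size, size)) < rng.uniform(0.1, 0.5)
            target = rng.uniform(0, 1, (size, size)) < rng.uniform(0.1, 0.5)
            if not pred.any() or not target.any():
                continue
            ours = surface_distances(pred, target)
            oracle = brute_force_surface(pred, target)
            assert ours[0] == pytest.approx(oracle[0], abs=1e-9)
            assert ours[1] == pytest.approx(oracle[1], abs=1e-9)

    def test_empty_mask_sentinel(self):
        t = np.zeros((6, 8), bool)
        full = np.ones((6, 8), bool)
        with pytest.warns(UserWarning):
            hd95, assd = surface_distances(t, full)
        assert hd95 == assd == pytest.approx(float(np.hypot(6, 8)))


class TestBoundaryF1:
    def test_identical_masks(self):
        t = np.zeros((10, 10), bool); t[3:7, 3:7] = True
        assert boundary_f1(t, t) == 1.0

    def test_one_pixel_shift_within_tolerance(self):
        a = np.zeros((12, 12), bool); a[3:7, 3:7] = True
        b = np.roll(a, 1, axis=1)
        assert boundary_f1(a, b, tolerance=2.0) == 1.0

    def test_five_pixel_shift_beyond_tolerance(self):
        # half-planes: each boundary is a single straight line, 5 px apart
        a = np.zeros((20, 20), bool); a[:3, :] = True
        b = np.zeros((20, 20), bool); b[:8, :] = True
        assert boundary_f1(a, b, tolerance=2.0) == 0.0


class TestECE:
    def test_perfectly_confident_and_correct(self):
        assert expected_calibration_error(np.ones(50), np.ones(50)) == 0.0

    def test_hand_binned_worked_example(self):
        conf = np.array([0.9, 0.9, 0.6, 0.6])
        correct = np.array([1.0, 0.0, 1.0, 1.0])
        # bins (0.5,0.6] and (0.8,0.9]: 0.5*|0.5-0.9| + 0.5*|1.0-0.6| = 0.4
        assert expected_calibration_error(conf, correct) == pytest.approx(0.4)

    def test_single_bin_reduction(self, rng):
        c = 0.83
        correct = (rng.uniform(0, 1, 1000) < 0.6).astype(float)
        ece = expected_calibration_error(np.full(1000, c), correct)
        assert ece == pytest.approx(abs(correct.mean() - c), abs=1e-12)

    def test_invariant_to_pixel_order(self, rng):
        conf = rng.uniform(0.5, 1.0, 500)
        correct = (rng.uniform(0, 1, 500) < conf).astype(float)
        perm = rng.permutation(500)
        assert expected_calibration_error(conf, correct) == pytest.approx(
            expected_calibration_error(conf[perm], correct[perm]), abs=1e-12)


class TestUEC:
    def test_perfect_correlation(self):
        e = np.array([1.0, 1.0, 0.0, 0.0])
        r = uncertainty_error_correlation(e.copy(), e)
        assert r.value == pytest.approx(1.0)
        assert not r.degenerate

    def test_constant_uncertainty_is_degenerate(self):
        r = uncertainty_error_correlation(np.full(10, 0.3),
                                          np.array([1, 0] * 5))
        assert r.value == 0.0 and r.degenerate

    def test_point_biserial_worked_example(self):
        r = uncertainty_error_correlation(np.array([0.9, 0.8, 0.1, 0.2]),
                                          np.array([1.0, 1.0, 0.0, 0.0]))
        # cov 0.175, sd_U 0.35355, sd_e 0.5 -> 0.98995
        assert r.value == pytest.approx(0.98995, abs=1e-5)


class TestPermutationTest:
    def test_identical_lists_give_one(self):
        a = [0.8, 0.7, 0.9, 0.6]
        assert paired_permutation_test(a, a) == 1.0

    def test_exhaustive_three_pairs(self):
        # differences [1,1,1]: 2 of the 8 sign patterns reach |mean| >= 1
        p = paired_permutation_test([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert p == pytest.approx(0.25)

    def test_type_one_error_rate_under_null(self):
        """Exchangeable null: rejection rate at alpha = 0.05 stays within
        binomial 95% bounds over 500 replicates."""
        from scipy.stats import binom
        rng = np.random.default_rng(7)
        n_rep = 500
        rejections = 0
        for rep in range(n_rep):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            p = paired_permutation_test(a, b, n_resamples=400, seed=rep)
            rejections += p <= 0.05
        lo = binom.ppf(0.025, n_rep, 0.05)
        hi = binom.ppf(0.975, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_p_value_in_unit_interval_with_plus_one_correction(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        p = paired_permutation_test(a, b, n_resamples=99, seed=0)
        assert 0.01 <= p <= 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            paired_permutation_test([1.0, 2.0], [1.0])
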