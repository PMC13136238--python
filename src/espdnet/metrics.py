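"""Region, boundary, calibration and significance metrics.

Region metrics follow the standard confusion-count definitions; surface
metrics (HD95, ASSD) use boundary pixels extracted by 8-connectivity erosion
and exact Euclidean nearest-neighbour distances, with HD95 the 95th
percentile (linear interpolation) of the *pooled* symmetric directed-distance
multiset and ASSD its mean.  Calibration is summarized by the expected
calibration error (equal-width, right-closed confidence bins) and by the
uncertainty-error correlation, implemented as the point-biserial Pearson
correlation between per-pixel uncertainty and the 0/1 error indicator.
Model comparisons use a paired sign-flip permutation test, exhaustive when
the number of sign patterns does not exceed the resample budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "EvalReport", "region_metrics", "surface_distances", "boundary_f1",
    "expected_calibration_error", "uncertainty_error_correlation",
    "UECResult", "paired_permutation_test", "boundary_pixels",
]


# --------------------------------------------------------------------------
# region metrics
# --------------------------------------------------------------------------

def region_metrics(pred_mask, target):
    """(dice, iou, precision, sensitivity) from confusion counts.

    Convention for degenerate cases: if both masks are empty all four
    metrics are 1; a zero denominator with a non-empty counterpart gives 0.
    """
    p = np.asarray(pred_mask).astype(bool)
    t = np.asarray(target).astype(bool)
    if p.shape != t.shape:
        raise ValueError("mask shape mismatch")
    tp = float(np.count_nonzero(p & t))
    fp = float(np.count_nonzero(p & ~t))
    fn = float(np.count_nonzero(~p & t))
    if tp + fp + fn == 0:
        return 1.0, 1.0, 1.0, 1.0
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    iou = tp / (tp + fp + fn)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    return dice, iou, precision, sensitivity


# --------------------------------------------------------------------------
# surface metrics
# --------------------------------------------------------------------------

_STRUCT8 = np.ones((3, 3), dtype=bool)


def boundary_pixels(mask) -> np.ndarray:
    """(n, 2) coordinates of boundary pixels: mask minus its 8-connectivity
    erosion, with outside-of-image treated as foreground (so a mask touching
    the border contributes its interior-facing contour; single pixels are
    their own boundary).  A mask with no interior-facing contour at all —
    e.g. the full frame — falls back to its border ring."""
    m = np.asarray(mask).astype(bool)
    eroded = ndi.binary_erosion(m, structure=_STRUCT8, border_value=1)
    pts = np.argwhere(m & ~eroded)
    if len(pts) == 0 and m.any():
        eroded = ndi.binary_erosion(m, structure=_STRUCT8, border_value=0)
        pts = np.argwhere(m & ~eroded)
    return pts


def surface_distances(pred, target):
    """(hd95, assd) in pixels over the pooled symmetric directed distances.

    Empty masks are degenerate: both values fall back to the image-diagonal
    sentinel and a warning is emitted.
    """
    p = np.asarray(pred).astype(bool)
    t = np.asarray(target).astype(bool)
    if p.shape != t.shape:
        raise ValueError("mask shape mismatch")
    if not p.any() or not t.any():
        warnings.warn("empty mask in surface_distances; returning diagonal sentinel")
        sentinel = float(np.hypot(*p.shape))
        return sentinel, sentinel
    bp = boundary_pixels(p)
    bt = boundary_pixels(t)
    d_pt, _ = cKDTree(bt).query(bp)
    d_tp, _ = cKDTree(bp).query(bt)
    pooled = np.concatenate([d_pt, d_tp])
    return float(np.percentile(pooled, 95)), float(pooled.mean())


def boundary_f1(pred, target, tolerance: float = 2.0) -> float:
    """F1 of boundary-pixel matching within a Euclidean ``tolerance``."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    p = np.asarray(pred).astype(bool)
    t = np.asarray(target).astype(bool)
    bp = boundary_pixels(p)
    bt = boundary_pixels(t)
    if len(bp) == 0 and len(bt) == 0:
        return 1.0
    if len(bp) == 0 or len(bt) == 0:
        return 0.0
    d_pt, _ = cKDTree(bt).query(bp)
    d_tp, _ = cKDTree(bp).query(bt)
    precision = float(np.mean(d_pt <= tolerance))
    recall = float(np.mean(d_tp <= tolerance))
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def expected_calibration_error(confidence, correct, n_bins: int = 10) -> float:
    """Sum_b (n_b / N) |acc_b - conf_b| over equal-width right-closed bins
    of [0, 1]."""
    conf = np.asarray(confidence, dtype=np.float64).ravel()
    corr = np.asarray(correct, dtype=np.float64).ravel()
    if conf.shape != corr.shape:
        raise ValueError("confidence/correct shape mismatch")
    # right-closed bins: (0, 1/n], (1/n, 2/n], ...; conf = 0 joins bin 0
    idx = np.clip(np.ceil(conf * n_bins).astype(int) - 1, 0, n_bins - 1)
    ece = 0.0
    n = conf.size
    for b in range(n_bins):
        sel = idx == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        ece += (nb / n) * abs(corr[sel].mean() - conf[sel].mean())
    return float(ece)


@dataclass
class UECResult:
    value: float
    degenerate: bool = False

    def __float__(self):
        return self.value


def uncertainty_error_correlation(u_map, error) -> UECResult:
    """Point-biserial Pearson correlation between per-pixel uncertainty and
    the 0/1 error indicator; degenerate (constant) inputs return 0 with the
    ``degenerate`` flag set."""
    u = np.asarray(u_map, dtype=np.float64).ravel()
    e = np.asarray(error, dtype=np.float64).ravel()
    if u.shape != e.shape:
        raise ValueError("shape mismatch")
    if np.ptp(u) == 0 or np.ptp(e) == 0:
        return UECResult(0.0, degenerate=True)
    r = np.corrcoef(u, e)[0, 1]
    return UECResult(float(r), degenerate=False)


# --------------------------------------------------------------------------
# significance
# --------------------------------------------------------------------------

def paired_permutation_test(scores_a, scores_b, n_resamples: int = 1000,
                            seed: int = 0) -> float:
    """Sign-flip test on paired differences; statistic |mean difference|.

    Exhaustive enumeration over all 2^n sign patterns when 2^n <= the
    resample budget, otherwise Monte-Carlo with the +1 correction
    p = (1 + #{|stat*| >= |stat|}) / (1 + n_resamples).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    observed = abs(d.mean())
    tol = 1e-12 * max(1.0, observed)
    if 2 ** n <= n_resamples:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        stats = np.abs((signs * d).mean(axis=1))
        return float(np.mean(stats >= observed - tol))
    rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_resamples, n))
    stats = np.abs((signs * d).mean(axis=1))
    return float((1 + np.count_nonzero(stats >= observed - tol)) / (1 + n_resamples))


# --------------------------------------------------------------------------
# report container
# --------------------------------------------------------------------------

_METRIC_COLS = ["dice", "iou", "precision", "sensitivity", "boundary_f1",
                "hd95", "assd"]


@dataclass
class EvalReport:
    """Per-sample metric table plus pooled calibration values."""
    per_sample: pd.DataFrame
    ece: float
    uec: UECResult
    p_values: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """mean +/- sd per metric over samples."""
        stats = self.per_sample[_METRIC_COLS].agg(["mean", "std"]).T
        stats.columns = ["mean", "sd"]
        return stats

    def summary(self) -> dict:
        agg = self.aggregate()
        out = {f"{k}_mean": float(agg.loc[k, "mean"]) for k in agg.index}
        out.update({f"{k}_sd": float(agg.loc[k, "sd"]) for k in agg.index})
        out["ece"] = self.ece
        out["uec"] = self.uec.value
        out["uec_degenerate"] = self.uec.degenerate
        out.update({f"p_{k}": v for k, v in self.p_values.items()})
        return out

    def to_json(self, path):
        import json
        from pathlib import Path
        Path(path).write_text(json.dumps(self.summary(), indent=2))

    def to_csv(self, path):
        self.per_sample.to_csv(path, index=False)
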