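"""Training, evaluation and prediction pipeline.

The protocol: AdamW (decoupled weight decay), ReduceLROnPlateau on the
validation Dice (patience 5, factor 0.5), early stopping (patience 20),
batch size 4, best-model selection by validation Dice.  Every source of
randomness — batch shuffling, augmentation, weight initialization — derives
from the single ``TrainConfig.seed``, so a rerun with identical inputs
reproduces the training log exactly.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import losses as L
from .data import SplitArrays, augment_pair, load_split
from .metrics import (EvalReport, boundary_f1, expected_calibration_error,
                      paired_permutation_test, region_metrics,
                      surface_distances, uncertainty_error_correlation)
from .model import ESPDNet, ModelConfig, load_checkpoint, save_checkpoint
from .nn import AdamW, ReduceLROnPlateau, Tensor, no_grad
from .phantom import DatasetManifest

__all__ = ["TrainConfig", "RunArtifacts", "train", "evaluate", "evaluate_model",
           "aggregate_reports", "predict"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 4
    max_epochs: int = 256
    scheduler_patience: int = 5
    scheduler_factor: float = 0.5
    early_stop_patience: int = 20
    input_size: int = 320
    seed: int = 0
    model_variant: str = "espd_full"
    profile: str = "full"          # "tiny" or "full" channel profile
    augment: bool = True
    loss: L.LossConfig = field(default_factory=L.LossConfig)

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("training hyperparameters must be positive")


@dataclass
class RunArtifacts:
    checkpoint_path: Path
    log_path: Path
    best_val_dice: float
    best_epoch: int
    epochs_run: int
    model: ESPDNet


def _model_config(cfg: TrainConfig) -> ModelConfig:
    maker = ModelConfig.tiny if cfg.profile == "tiny" else ModelConfig.full
    return maker(variant=cfg.model_variant, seed=cfg.seed)


def _forward_loss(model: ESPDNet, images, masks, epoch: int, cfg: TrainConfig):
    out = model(images)
    pred = out.m_refined[:, 0]
    target = masks[:, 0]
    dice = L.dice_loss(pred, target)
    focal = L.focal_loss(pred, target, gamma=cfg.loss.focal_gamma,
                         alpha_f=cfg.loss.focal_alpha)
    boundary = L.boundary_loss(pred, target, normalize=True)
    liver = L.liver_loss(dice, focal, boundary, cfg.loss)
    liver_value = float(liver.data)      # weighted-sum identity, pre-auxiliary
    if out.evidence is not None:
        alpha0 = out.evidence.fields[-1].alpha       # (B, 2, H/2, W/2)
        t_small = masks[:, 0, ::2, ::2]              # nearest downsample
        onehot = np.stack([1.0 - t_small, t_small], axis=1)
        edl = L.edl_loss(alpha0, onehot, axis=1)
        if cfg.loss.deep_supervision:
            # auxiliary Dice on the expected foreground of every scale
            for f in out.evidence.fields:
                stride = masks.shape[-1] // f.p.shape[-1]
                t_s = masks[:, 0, ::stride, ::stride]
                liver = liver + cfg.loss.deep_supervision_weight * \
                    L.dice_loss(f.p[:, 1], t_s)
    else:
        edl = Tensor(np.zeros((), dtype=np.float32))
    total = L.total_loss(liver, edl, epoch, cfg.loss)
    breakdown = L.LossBreakdown(dice=float(dice.data), focal=float(focal.data),
                                boundary=float(boundary.data),
                                liver=liver_value, edl=float(edl.data),
                                total=float(total.data))
    return total, breakdown, out


def _val_dice(model: ESPDNet, val: SplitArrays, batch: int) -> float:
    dices = []
    with no_grad():
        for i in range(0, len(val), batch):
            out = model(val.images[i:i + batch])
            pred = out.m_refined.data[:, 0] >= 0.5
            for p, t in zip(pred, val.masks[:, 0][i:i + batch]):
                dices.append(region_metrics(p, t)[0])
    return float(np.mean(dices))


def train(manifest: DatasetManifest, cfg: TrainConfig, out_dir) -> RunArtifacts:
    """Train the selected variant; returns artifacts incl. the best model."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tr = load_split(manifest, "train")
    va = load_split(manifest, "val")
    model = ESPDNet(_model_config(cfg))
    opt = AdamW(model.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, mode="max", patience=cfg.scheduler_patience,
                              factor=cfg.scheduler_factor)
    rng = np.random.default_rng(cfg.seed)
    n = len(tr)
    best_dice, best_epoch, best_state = -1.0, -1, None
    since_best = 0
    log_path = out / "training_log.csv"
    rows = []
    for epoch in range(cfg.max_epochs):
        t0 = time.time()
        order = rng.permutation(n)
        ep_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if cfg.augment:
                imgs, msks = [], []
                for j in idx:
                    aug_seed = int(rng.integers(0, 2 ** 31 - 1))
                    i2, m2 = augment_pair(tr.images[j, 0], tr.masks[j, 0], aug_seed)
                    imgs.append(i2[None])
                    msks.append(m2[None])
                images, masks = np.stack(imgs), np.stack(msks)
            else:
                images, masks = tr.images[idx], tr.masks[idx]
            total, breakdown, _ = _forward_loss(model, images, masks, epoch, cfg)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={float(total.data)}; "
                    f"breakdown={breakdown}")
            model.zero_grad()
            total.backward()
            opt.step()
            ep_losses.append(breakdown)
        vd = _val_dice(model, va, cfg.batch_size)
        sched.step(vd)
        mean = lambda key: float(np.mean([getattr(b, key) for b in ep_losses]))
        rows.append({"epoch": epoch, "dice_loss": mean("dice"),
                     "focal_loss": mean("focal"), "boundary_loss": mean("boundary"),
                     "liver_loss": mean("liver"), "edl_loss": mean("edl"),
                     "total_loss": mean("total"), "val_dice": vd,
                     "lr": opt.lr, "seconds": round(time.time() - t0, 3)})
        if vd > best_dice:
            best_dice, best_epoch = vd, epoch
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    with open(log_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    model.load_state_dict(best_state)
    ckpt = out / "best.ckpt.npz"
    save_checkpoint(model, ckpt, extra={"best_val_dice": best_dice,
                                        "best_epoch": best_epoch,
                                        "epochs_run": len(rows),
                                        "seed": cfg.seed})
    return RunArtifacts(checkpoint_path=ckpt, log_path=log_path,
                        best_val_dice=best_dice, best_epoch=best_epoch,
                        epochs_run=len(rows), model=model)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def evaluate_model(model: ESPDNet, split_arrays: SplitArrays,
                   batch: int = 4, threshold: float = 0.5) -> EvalReport:
    """All metrics on one split: per-sample region/boundary metrics plus
    pooled calibration (ECE on the confidence map, UEC on the uncertainty
    map against the 0/1 error indicator)."""
    import pandas as pd
    rows = []
    confs, corrects, us, errs = [], [], [], []
    coarse_hd = []
    with no_grad():
        for i in range(0, len(split_arrays), batch):
            out = model(split_arrays.images[i:i + batch])
            preds = out.m_refined.data[:, 0]
            coarse = out.m_coarse.data[:, 0]
            u = out.uncertainty.data[:, 0]
            for b in range(preds.shape[0]):
                t = split_arrays.masks[i + b, 0].astype(bool)
                p = preds[b] >= threshold
                dice, iou, prec, sens = region_metrics(p, t)
                hd95, assd = surface_distances(p, t)
                bf1 = boundary_f1(p, t)
                hd95_c, _ = surface_distances(coarse[b] >= threshold, t)
                coarse_hd.append(hd95_c)
                rows.append({"dice": dice, "iou": iou, "precision": prec,
                             "sensitivity": sens, "boundary_f1": bf1,
                             "hd95": hd95, "assd": assd,
                             "hd95_coarse": hd95_c})
                confs.append(out.confidence[b, 0].ravel())
                corrects.append((p == t).ravel().astype(float))
                us.append(u[b].ravel())
                errs.append((p != t).ravel().astype(float))
    ece = expected_calibration_error(np.concatenate(confs), np.concatenate(corrects))
    uec = uncertainty_error_correlation(np.concatenate(us), np.concatenate(errs))
    return EvalReport(per_sample=pd.DataFrame(rows), ece=ece, uec=uec)


def evaluate(checkpoint_path, manifest: DatasetManifest, split: str = "test",
             compare_checkpoint=None, n_resamples: int = 1000,
             seed: int = 0) -> EvalReport:
    """Evaluate a checkpoint on a manifest split; optionally run the paired
    permutation test (per-sample Dice) against a second checkpoint."""
    model, _ = load_checkpoint(checkpoint_path)
    arrays = load_split(manifest, split)
    report = evaluate_model(model, arrays)
    if compare_checkpoint is not None:
        other, _ = load_checkpoint(compare_checkpoint)
        other_report = evaluate_model(other, arrays)
        p = paired_permutation_test(report.per_sample.dice.to_numpy(),
                                    other_report.per_sample.dice.to_numpy(),
                                    n_resamples=n_resamples, seed=seed)
        report.p_values["dice_vs_compare"] = p
    return report


def aggregate_reports(reports):
    """Mean +/- sd of every summary quantity over repeated runs (e.g. the
    multi-seed protocol); returns a DataFrame indexed by quantity."""
    import pandas as pd
    rows = [r.summary() for r in reports]
    df = pd.DataFrame(rows).select_dtypes("number")
    out = df.agg(["mean", "std"]).T
    out.columns = ["mean", "sd"]
    return out


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def predict(checkpoint_path, image_path, out_dir,
            export_uncertainty: bool = False, export_edges: bool = False):
    """Segment one image and write mask/heatmap PNGs; returns written paths."""
    import imageio.v2 as imageio
    model, _ = load_checkpoint(checkpoint_path)
    img = np.asarray(imageio.imread(image_path), dtype=np.float32)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if img.max() > 1.5:
        img /= 255.0
    out = model.predict(img[None, None])
    outp = Path(out_dir)
    outp.mkdir(parents=True, exist_ok=True)
    stem = Path(image_path).stem

    def _save(name, arr):
        path = outp / f"{stem}_{name}.png"
        imageio.imwrite(path, np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8))
        return path

    written = [
        _save("mask", (out.m_refined.data[0, 0] >= 0.5).astype(float)),
        _save("coarse", out.m_coarse.data[0, 0]),
        _save("uncertainty", out.uncertainty.data[0, 0]),
    ]
    np.save(outp / f"{stem}_uncertainty.npy",
            out.uncertainty.data[0, 0].astype(np.float32))
    if export_uncertainty:
        for k, u in enumerate(out.uncertainty_maps):
            written.append(_save(f"uncertainty_s{len(out.uncertainty_maps) - 1 - k}",
                                 u[0]))
    if export_edges:
        e = out.edges
        peak = max(float(np.max(e.E_sobel)), 1e-8)
        written.append(_save("edge_sobel", e.E_sobel[0, 0] / peak))
        written.append(_save("edge_semantic", e.E_sem.data[0, 0]))
        written.append(_save("edge_fused", e.E_boundary.data[0, 0]))
        if out.a_boundary is not None:
            written.append(_save("boundary_attention", out.a_boundary.data[0, 0]))
    return written
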