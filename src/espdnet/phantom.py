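"""Synthetic ultrasound speckle phantoms with diffuse, blurred-boundary nodules.

The generator emulates the statistical regime of B-mode liver-fibrosis
ultrasound at desk scale: a speckle-textured single-channel image in [0, 1],
nodules occupying a small fraction of the field (3%-8% by default), gradual
grayscale transitions at nodule margins and substantial intensity overlap
between lesion and parenchyma.  Four nodule morphologies are covered —
cord-like fragments, dispersed small particles, massive dense clusters and
fusiform low-contrast spindles — plus a ``mixed`` regime drawing uniformly
among them.

Speckle is modelled as a multiplicative gamma field (mean 1, shape
``speckle_shape``), lightly smoothed so the grain has finite spatial
correlation; gradual boundaries come from Gaussian-blurring the clean
intensity field before the noise is applied.  This is a phenomenological
surrogate, not an acoustic simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "PhantomConfig", "UltrasoundSample", "DatasetManifest",
    "generate_phantom", "generate_dataset", "histogram_overlap",
]

SCENARIOS = ("cord", "particles", "dense", "fusiform", "mixed")

# default nodule-count ranges per morphology
_COUNTS = {"cord": (2, 6), "particles": (8, 25), "dense": (4, 10), "fusiform": (1, 3)}


@dataclass(frozen=True)
class PhantomConfig:
    height: int = 320
    width: int = 320
    scenario: str = "mixed"
    nodule_count_range: tuple[int, int] | None = None
    foreground_fraction_range: tuple[float, float] = (0.03, 0.08)
    contrast_delta: float = 0.15
    boundary_blur_sigma: float = 2.0
    speckle_shape: float = 25.0
    shadow_probability: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom size must be at least 32x32")
        lo, hi = self.foreground_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("foreground_fraction_range must be inside (0, 1)")
        if self.boundary_blur_sigma < 0:
            raise ValueError("boundary_blur_sigma must be >= 0")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be > 0")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class UltrasoundSample:
    image: np.ndarray          # float32 H x W in [0, 1]
    mask: np.ndarray           # uint8 H x W in {0, 1}
    scenario: str
    seed: int
    split: str = ""


@dataclass
class DatasetManifest:
    entries: pd.DataFrame      # columns: id, image, mask, split
    split_ratios: tuple[float, float, float]
    config: PhantomConfig

    def paths(self, split: str | None = None):
        df = self.entries if split is None else self.entries[self.entries["split"] == split]
        return list(zip(df["image"], df["mask"]))


# --------------------------------------------------------------------------
# mask geometry
# --------------------------------------------------------------------------

def _disk_paint(mask, cy, cx, r):
    h, w = mask.shape
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r


def _draw_cord(rng, shape, scale):
    """One elongated curved strip: disks painted along a random quadratic arc."""
    h, w = shape
    m = np.zeros(shape, dtype=bool)
    p0 = rng.uniform([0.15 * h, 0.15 * w], [0.85 * h, 0.85 * w])
    ang = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(0.2, 0.45) * min(h, w) * scale
    p2 = p0 + length * np.array([np.sin(ang), np.cos(ang)])
    mid = 0.5 * (p0 + p2) + rng.normal(0, 0.08 * length, 2)
    width = max(1.0, rng.uniform(0.015, 0.03) * min(h, w) * scale)
    for t in np.linspace(0, 1, max(8, int(length))):
        pt = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * mid + t ** 2 * p2
        _disk_paint(m, pt[0], pt[1], width)
    return m


def _draw_ellipse(rng, shape, r_range, aspect_range, scale):
    h, w = shape
    m = np.zeros(shape, dtype=bool)
    cy = rng.uniform(0.1 * h, 0.9 * h)
    cx = rng.uniform(0.1 * w, 0.9 * w)
    a = rng.uniform(*r_range) * min(h, w) * scale
    b = a * rng.uniform(*aspect_range)
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    m |= (u / max(a, 1.0)) ** 2 + (v / max(b, 1.0)) ** 2 <= 1.0
    return m


def _scenario_mask(rng, cfg: PhantomConfig, scenario: str, scale: float):
    """Draw one candidate mask; returns (mask, drawn_count)."""
    shape = (cfg.height, cfg.width)
    lo, hi = cfg.nodule_count_range or _COUNTS[scenario]
    n = int(rng.integers(lo, hi + 1))
    mask = np.zeros(shape, dtype=bool)
    if scenario == "cord":
        for _ in range(n):
            mask |= _draw_cord(rng, shape, scale)
    elif scenario == "particles":
        for _ in range(n):
            mask |= _draw_ellipse(rng, shape, (0.02, 0.05), (0.6, 1.0), scale)
    elif scenario == "fusiform":
        for _ in range(n):
            mask |= _draw_ellipse(rng, shape, (0.08, 0.16), (0.25, 0.4), scale)
    elif scenario == "dense":
        # closely packed but non-touching: enforce a >=1 px gap via dilation
        placed = 0
        struct = np.ones((3, 3), dtype=bool)
        tries = 0
        while placed < n and tries < 200:
            tries += 1
            cand = _draw_ellipse(rng, shape, (0.04, 0.08), (0.6, 1.0), scale)
            if not cand.any():
                continue
            grown = ndi.binary_dilation(cand, structure=struct)
            if (grown & mask).any():
                continue
            mask |= cand
            placed += 1
        if placed < n:          # failed packing counts as a rejected attempt
            return np.zeros(shape, dtype=bool), 0
    return mask, n


# --------------------------------------------------------------------------
# image synthesis
# --------------------------------------------------------------------------

def _speckle_field(rng, shape, speckle_shape):
    field = rng.gamma(speckle_shape, 1.0 / speckle_shape, size=shape)
    field = ndi.gaussian_filter(field, 0.8, mode="reflect")
    return field / field.mean()


def generate_phantom(config: PhantomConfig, sample_seed: int) -> UltrasoundSample:
    """Generate one image/mask pair, bit-identical for identical inputs.

    Raises ``RuntimeError`` if rejection sampling cannot hit the configured
    foreground fraction within 100 attempts (with geometric rescaling of the
    nodule sizes as a fallback after each miss).
    """
    if sample_seed < 0:
        raise ValueError("sample_seed must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(sample_seed)]))
    scenario = config.scenario
    if scenario == "mixed":
        scenario = str(rng.choice(["cord", "particles", "dense", "fusiform"]))
    lo, hi = config.foreground_fraction_range
    target = 0.5 * (lo + hi)
    scale = 1.0
    mask = None
    for _ in range(100):
        cand, n = _scenario_mask(rng, config, scenario, scale)
        frac = cand.mean()
        if lo <= frac <= hi and n > 0:
            mask = cand
            break
        if frac > 0:
            # geometric rescaling fallback: area scales ~ scale^2
            scale = float(np.clip(scale * np.sqrt(target / frac), 0.2, 5.0))
    if mask is None:
        raise RuntimeError(
            f"could not reach foreground fraction {config.foreground_fraction_range} "
            f"for scenario={scenario!r} at {config.height}x{config.width} after 100 attempts")

    delta = config.contrast_delta * (0.5 if scenario == "fusiform" else 1.0)
    hetero = ndi.gaussian_filter(
        rng.standard_normal((config.height, config.width)),
        0.12 * min(config.height, config.width), mode="reflect")
    hetero /= max(hetero.std(), 1e-8)
    background = 0.45 + 0.03 * hetero
    clean = background + delta * mask
    clean = ndi.gaussian_filter(clean, config.boundary_blur_sigma, mode="reflect")
    image = clean * _speckle_field(rng, clean.shape, config.speckle_shape)

    if rng.uniform() < config.shadow_probability:
        # acoustic shadow: dark vertical band with soft edges
        x0 = rng.uniform(0, config.width)
        bw = rng.uniform(0.05, 0.15) * config.width
        xs = np.arange(config.width)
        band = 1.0 - 0.5 * np.exp(-0.5 * ((xs - x0) / (0.5 * bw)) ** 2)
        image = image * band[None, :]

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return UltrasoundSample(image=image, mask=mask.astype(np.uint8),
                            scenario=scenario, seed=int(sample_seed))


def split_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """round(n * ratio) for val/test, remainder assigned to train."""
    n_val = int(round(n * ratios[1]))
    n_test = int(round(n * ratios[2]))
    return n - n_val - n_test, n_val, n_test


def generate_dataset(config: PhantomConfig, n: int,
                     split_ratios: tuple[float, float, float],
                     out_dir, seed: int) -> DatasetManifest:
    """Write ``n`` image/mask PNG pairs plus a CSV manifest and JSON sidecar."""
    if n < 10:
        raise ValueError("n must be >= 10")
    if abs(sum(split_ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(config, seed=int(seed))
    n_train, n_val, n_test = split_sizes(n, split_ratios)
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    rows = []
    for i in range(n):
        sample = generate_phantom(cfg, sample_seed=i)
        sid = f"phantom_{i:05d}"
        img_path = out / "images" / f"{sid}.png"
        msk_path = out / "masks" / f"{sid}.png"
        imageio.imwrite(img_path, np.round(sample.image * 255).astype(np.uint8))
        imageio.imwrite(msk_path, (sample.mask * 255).astype(np.uint8))
        rows.append({"id": sid, "image": str(img_path), "mask": str(msk_path),
                     "split": splits[i]})
    entries = pd.DataFrame(rows)
    entries.to_csv(out / "manifest.csv", index=False)
    sidecar = dataclasses.asdict(cfg)
    sidecar["n"] = n
    sidecar["split_ratios"] = list(split_ratios)
    (out / "manifest.json").write_text(json.dumps(sidecar, indent=2))
    return DatasetManifest(entries=entries, split_ratios=tuple(split_ratios), config=cfg)


def load_manifest(out_dir) -> DatasetManifest:
    out = Path(out_dir)
    entries = pd.read_csv(out / "manifest.csv")
    meta = json.loads((out / "manifest.json").read_text())
    ratios = tuple(meta.pop("split_ratios"))
    meta.pop("n", None)
    meta["nodule_count_range"] = (tuple(meta["nodule_count_range"])
                                  if meta["nodule_count_range"] else None)
    meta["foreground_fraction_range"] = tuple(meta["foreground_fraction_range"])
    cfg = PhantomConfig(**meta)
    return DatasetManifest(entries=entries, split_ratios=ratios, config=cfg)


def histogram_overlap(image: np.ndarray, mask: np.ndarray, bins: int = 64) -> float:
    """Overlap coefficient between foreground and background intensity
    histograms (sum of bin-wise minima of the two densities; 1 = identical)."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    fg, _ = np.histogram(image[mask > 0], bins=edges, density=True)
    bg, _ = np.histogram(image[mask == 0], bins=edges, density=True)
    width = edges[1] - edges[0]
    return float(np.minimum(fg, bg).sum() * width)
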