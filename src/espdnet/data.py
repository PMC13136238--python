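"""Dataset access and synchronized augmentation.

Augmentation applies the *same* geometric transform (horizontal flip p=0.5,
rotation +/-15 degrees, isotropic scale +/-10%) to image and mask — linear
interpolation for the image, nearest neighbour for the mask so it stays
strictly binary — and pixel transforms (brightness/contrast +/-20%, additive
Gaussian noise) to the image only.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v2 as imageio
import numpy as np
from scipy import ndimage as ndi

from .phantom import DatasetManifest

__all__ = ["augment_pair", "load_pair", "load_split", "SplitArrays"]


@dataclass
class SplitArrays:
    images: np.ndarray   # (N, 1, H, W) float32 in [0, 1]
    masks: np.ndarray    # (N, 1, H, W) float32 in {0, 1}

    def __len__(self):
        return len(self.images)


def load_pair(image_path, mask_path):
    img = np.asarray(imageio.imread(image_path), dtype=np.float32)
    img /= 255.0 if img.max() > 1.5 else 1.0
    msk = (np.asarray(imageio.imread(mask_path)) > 127).astype(np.float32)
    return img, msk


def load_split(manifest: DatasetManifest, split: str) -> SplitArrays:
    pairs = manifest.paths(split)
    if not pairs:
        raise ValueError(f"split {split!r} is empty")
    imgs, msks = [], []
    for ip, mp in pairs:
        i, m = load_pair(ip, mp)
        imgs.append(i[None])
        msks.append(m[None])
    return SplitArrays(images=np.stack(imgs), masks=np.stack(msks))


def _affine(arr: np.ndarray, angle_deg: float, scale: float, order: int) -> np.ndarray:
    """Rotate-and-scale about the image centre in a single resampling."""
    h, w = arr.shape
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]]) / scale
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = centre - rot @ centre
    return ndi.affine_transform(arr, rot, offset=offset, order=order,
                                mode="reflect", prefilter=(order > 1))


def augment_pair(image: np.ndarray, mask: np.ndarray, seed: int):
    """Deterministic synchronized augmentation of one (image, mask) pair."""
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float32)
    msk = np.asarray(mask, dtype=np.float32)

    if rng.uniform() < 0.5:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()
    angle = rng.uniform(-15.0, 15.0)
    scale = rng.uniform(0.9, 1.1)
    img = _affine(img, angle, scale, order=1)
    msk = _affine(msk, angle, scale, order=0)

    # pixel transforms on the image only
    img = img * rng.uniform(0.8, 1.2) + rng.uniform(-0.2, 0.2) * img.mean()
    img = img + rng.normal(0.0, rng.uniform(0.0, 0.02), size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    msk = (msk > 0.5).astype(np.float32)
    return img, msk
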