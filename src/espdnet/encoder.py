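"""Four-stage downsampling encoder with hybrid channel/spatial attention.

Stages 0-1 use lightweight squeeze-and-excitation (SE) channel recalibration,
tuned to low-level texture and edge features; stages 2-3 use CBAM
(channel-then-spatial) attention for semantic dependencies.  Each stage
halves the spatial resolution, so the pyramid sits at strides 2/4/8/16
relative to the input.  Group normalization keeps the blocks independent of
the (small) batch size.

An ``identity_gates`` switch forces every attention gate to exactly 1,
reducing the encoder to a plain convolutional downsampler — the ablation
anchor used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Conv2d, GroupNorm, Linear, Module, Tensor, avg_pool2,
                 concat)

__all__ = ["EncoderConfig", "FeaturePyramid", "SEBlock", "CBAMBlock", "Encoder"]


@dataclass(frozen=True)
class EncoderConfig:
    in_channels: int = 1
    stage_channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    se_reduction: int = 4
    cbam_kernel: int = 7
    identity_gates: bool = False

    def __post_init__(self):
        if len(self.stage_channels) != 4:
            raise ValueError("encoder has exactly 4 stages")
        if any(b <= a for a, b in zip(self.stage_channels, self.stage_channels[1:])):
            raise ValueError("stage channels must be strictly increasing")
        if self.cbam_kernel % 2 == 0:
            raise ValueError("cbam_kernel must be odd")
        for c in self.stage_channels[:2]:
            if c % self.se_reduction:
                raise ValueError("se_reduction must divide SE-stage channels")


@dataclass
class FeaturePyramid:
    """Feature maps at strides 2/4/8/16 (s0 finest, s3 coarsest)."""
    s0: Tensor
    s1: Tensor
    s2: Tensor
    s3: Tensor

    def __iter__(self):
        return iter((self.s0, self.s1, self.s2, self.s3))


class SEBlock(Module):
    """Channel recalibration: global average pool -> bottleneck MLP -> sigmoid gate."""

    def __init__(self, channels: int, reduction: int, rng, identity: bool = False):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.identity = identity

    def gate(self, x: Tensor) -> Tensor:
        z = x.mean(axis=(2, 3))                   # (B, C)
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if self.identity:
            return x
        B, C, _, _ = x.shape
        return x * self.gate(x).reshape(B, C, 1, 1)


class CBAMBlock(Module):
    """Channel attention followed by spatial attention (pooled-descriptor conv)."""

    def __init__(self, channels: int, rng, kernel: int = 7, reduction: int = 4,
                 identity: bool = False):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.spatial = Conv2d(2, 1, kernel, rng)
        self.identity = identity

    def channel_gate(self, x: Tensor) -> Tensor:
        B, C, _, _ = x.shape
        avg = x.mean(axis=(2, 3))
        mx = x.reshape(B, C, -1).max(axis=2)
        z = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return z.sigmoid().reshape(B, C, 1, 1)

    def spatial_gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.spatial(concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if self.identity:
            return x
        x = x * self.channel_gate(x)
        return x * self.spatial_gate(x)


class _Stage(Module):
    """Two 3x3 conv + group norm + ReLU at the incoming resolution, then
    attention, then 2x2 mean-pool downsampling — so fine structure is seen
    by full-resolution convolutions before any information is discarded."""

    def __init__(self, c_in: int, c_out: int, attention: Module, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.norm1 = GroupNorm(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.norm2 = GroupNorm(c_out)
        self.attention = attention

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(self.conv1(x)).relu()
        x = self.norm2(self.conv2(x)).relu()
        return avg_pool2(self.attention(x))


class Encoder(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        cs = config.stage_channels
        ident = config.identity_gates
        atts = [
            SEBlock(cs[0], config.se_reduction, rng, identity=ident),
            SEBlock(cs[1], config.se_reduction, rng, identity=ident),
            CBAMBlock(cs[2], rng, kernel=config.cbam_kernel, identity=ident),
            CBAMBlock(cs[3], rng, kernel=config.cbam_kernel, identity=ident),
        ]
        c_prev = config.in_channels
        stages = []
        for c, att in zip(cs, atts):
            stages.append(_Stage(c_prev, c, att, rng))
            c_prev = c
        self.stages = stages

    def forward(self, image: Tensor) -> FeaturePyramid:
        """Encode a (B, C, H, W) image; H and W must be divisible by 16."""
        _, _, H, W = image.shape
        if H % 16 or W % 16:
            raise ValueError(f"input size {H}x{W} must be divisible by 16")
        feats = []
        x = image
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return FeaturePyramid(*feats)
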