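"""Semantic-probabilistic dual-path fusion bottleneck.

Two parallel pathways are fused at the stride-8 grid:

* a **semantic path** of deformable convolutions over the stride-8 encoder
  features, whose learned per-location sampling offsets adapt the receptive
  field to irregular nodule morphology (offsets are zero-initialized, so at
  initialization the path is an ordinary convolution stack);
* a **probabilistic path** of window-based self-attention over the stride-16
  features (attention restricted to non-overlapping WxW windows, dropping the
  cost from O(N^2) to O(N W^2)), upsampled back to the stride-8 grid.

The per-location variance across channels of the attention output — a proxy
for the model's local certainty — is projected to a single-channel
probabilistic attention map ``A_prob`` (learnable affine, so the network
chooses the polarity).  The semantic features are modulated multiplicatively,

    F_guided = F_sem * (1 + alpha * sigmoid(A_prob)),

with ``alpha`` learnable and initialized at 0 (identity modulation), then the
two paths are merged by a pointwise feed-forward network with a residual
projection of the bottleneck input:

    s_final = FFN(concat[F_guided, F_prob]) + proj(input).

With ``alpha = 0`` and zero FFN weights the whole block is a pure residual
pass-through, the anchor used by the ablation switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Conv2d, GroupNorm, Module, Parameter, Tensor, concat,
                 deform_sample, softmax, upsample2)

__all__ = ["SPDFConfig", "DualPathFeatures", "DeformConv2d", "WindowAttention",
           "SPDFBottleneck", "probability_guided_fusion"]


@dataclass(frozen=True)
class SPDFConfig:
    window: int = 4
    deform_kernel: int = 3
    ffn_expansion: int = 2
    n_heads: int = 1
    attn_dim: int = 16

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.deform_kernel % 2 == 0:
            raise ValueError("deform_kernel must be odd")


@dataclass
class DualPathFeatures:
    F_sem: Tensor
    F_prob: Tensor
    variance: Tensor       # raw per-location channel variance of F_prob
    A_prob: Tensor         # single-channel probabilistic attention map
    F_guided: Tensor
    s_final: Tensor
    attn_scores: np.ndarray | None = None   # (B, nW, W^2, W^2) when requested


class DeformConv2d(Module):
    """Deformable convolution: a 3x3 conv predicts per-tap offsets
    (zero-initialized), bilinear sampling gathers the deformed taps, and a
    1x1 convolution over the stacked taps applies the kernel weights."""

    def __init__(self, c_in: int, c_out: int, rng, kernel: int = 3):
        self.kernel = kernel
        self.offset_conv = Conv2d(c_in, 2 * kernel * kernel, 3, rng, zero_init=True)
        self.weight_conv = Conv2d(c_in * kernel * kernel, c_out, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        offsets = self.offset_conv(x)
        sampled = deform_sample(x, offsets, kernel=self.kernel)
        return self.weight_conv(sampled)

    def as_standard_kernel(self) -> np.ndarray:
        """The equivalent dense kernel (c_out, c_in, k, k) at zero offsets."""
        c_out = self.weight_conv.weight.shape[0]
        k = self.kernel
        c_in = self.weight_conv.weight.shape[1] // (k * k)
        return self.weight_conv.weight.data.reshape(c_out, k * k, c_in).transpose(
            0, 2, 1).reshape(c_out, c_in, k, k).transpose(0, 1, 2, 3).copy()


class WindowAttention(Module):
    """Single-head self-attention within non-overlapping WxW windows, with a
    learned per-window positional bias shared across windows."""

    def __init__(self, channels: int, window: int, dim: int, rng):
        self.window = window
        self.dim = dim
        self.q = Conv2d(channels, dim, 1, rng, bias=False)
        self.k = Conv2d(channels, dim, 1, rng, bias=False)
        self.v = Conv2d(channels, channels, 1, rng)
        self.proj = Conv2d(channels, channels, 1, rng)
        self.pos_bias = Parameter(np.zeros((window * window, window * window)))

    def _windows(self, t: Tensor):
        B, C, H, W = t.shape
        w = self.window
        # (B, C, H/w, w, W/w, w) -> (B, nW, w*w, C)
        return (t.reshape(B, C, H // w, w, W // w, w)
                 .transpose(0, 2, 4, 3, 5, 1)
                 .reshape(B, (H // w) * (W // w), w * w, C))

    def _unwindows(self, t: Tensor, shape):
        B, C, H, W = shape
        w = self.window
        return (t.reshape(B, H // w, W // w, w, w, C)
                 .transpose(0, 5, 1, 3, 2, 4)
                 .reshape(B, C, H, W))

    def forward(self, x: Tensor, return_scores: bool = False):
        B, C, H, W = x.shape
        if H % self.window or W % self.window:
            raise ValueError(f"spatial size {H}x{W} not divisible by window {self.window}")
        q = self._windows(self.q(x))
        k = self._windows(self.k(x))
        v = self._windows(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dim)) + self.pos_bias
        attn = softmax(scores, axis=-1)
        out = self._unwindows(attn @ v, (B, C, H, W))
        out = self.proj(out) + x
        return (out, attn.data.copy()) if return_scores else (out, None)


def probability_guided_fusion(F_sem: Tensor, A_prob: Tensor, alpha) -> Tensor:
    """F_guided = F_sem * (1 + alpha * sigmoid(A_prob)); A_prob broadcasts
    over channels.  The multiplier lies in [1, 1+alpha] for alpha >= 0, so
    enhancement never suppresses the semantic features below identity."""
    if not isinstance(alpha, Tensor):
        alpha = Tensor(np.asarray(alpha, dtype=np.float32))
    return F_sem * (1.0 + alpha * A_prob.sigmoid())


class SPDFBottleneck(Module):
    """Fuses the stride-8 (semantic) and stride-16 (probabilistic) encoder
    features into the bottleneck map consumed by the decoder."""

    def __init__(self, c_sem: int, c_prob: int, c_out: int, config: SPDFConfig,
                 rng: np.random.Generator, enabled: bool = True):
        self.config = config
        self.enabled = enabled
        self.residual_proj = Conv2d(c_sem, c_out, 1, rng)
        if enabled:
            self.deform1 = DeformConv2d(c_sem, c_sem, rng, kernel=config.deform_kernel)
            self.norm_sem = GroupNorm(c_sem)
            self.deform2 = DeformConv2d(c_sem, c_sem, rng, kernel=config.deform_kernel)
            self.attn = WindowAttention(c_prob, config.window, config.attn_dim, rng)
            self.prob_proj = Conv2d(c_prob, c_sem, 1, rng)
            self.var_proj = Conv2d(1, 1, 1, rng)
            hidden = config.ffn_expansion * c_out
            self.ffn1 = Conv2d(2 * c_sem, hidden, 1, rng)
            self.ffn2 = Conv2d(hidden, c_out, 1, rng, zero_init=True)
            self.alpha = Parameter(np.zeros(()))

    def semantic_path(self, F: Tensor) -> Tensor:
        return self.deform2(self.norm_sem(self.deform1(F)).relu())

    def probabilistic_path(self, F: Tensor, return_scores: bool = False):
        """Windowed self-attention on the coarse grid, upsampled to the fusion
        grid; returns (F_prob, variance, A_prob[, scores])."""
        out, scores = self.attn(F, return_scores=return_scores)
        F_prob = upsample2(self.prob_proj(out))
        mu = F_prob.mean(axis=1, keepdims=True)
        centered = F_prob - mu
        variance = (centered * centered).mean(axis=1, keepdims=True)
        A_prob = self.var_proj(variance)
        return F_prob, variance, A_prob, scores

    def fuse(self, F_guided: Tensor, F_prob: Tensor, residual: Tensor) -> Tensor:
        return self.ffn2(self.ffn1(concat([F_guided, F_prob], axis=1)).relu()) + residual

    def forward(self, s2: Tensor, s3: Tensor,
                return_scores: bool = False) -> DualPathFeatures:
        residual = self.residual_proj(s2)
        if not self.enabled:
            return DualPathFeatures(F_sem=s2, F_prob=s2, variance=s2, A_prob=s2,
                                    F_guided=s2, s_final=residual)
        F_sem = self.semantic_path(s2)
        F_prob, variance, A_prob, scores = self.probabilistic_path(
            s3, return_scores=return_scores)
        F_guided = probability_guided_fusion(F_sem, A_prob, self.alpha)
        s_final = self.fuse(F_guided, F_prob, residual)
        return DualPathFeatures(F_sem=F_sem, F_prob=F_prob, variance=variance,
                                A_prob=A_prob, F_guided=F_guided, s_final=s_final,
                                attn_scores=scores)
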