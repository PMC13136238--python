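"""Dirichlet boundary-aware refinement.

A coarse mask is corrected only where correction is warranted.  Three cues
are aggregated into a boundary attention map ``A_boundary``:

* the decoder's epistemic uncertainty map U (high at ambiguous tissue),
* probabilistic ambiguity ``1 - 2|M_coarse - 0.5|`` (peaks at p = 0.5),
* a fused edge map combining Sobel gradients of the raw image with a
  learnable semantic-edge head on high-level features.

The refinement itself is a gated residual,

    M_refined = clamp(M_coarse + A_boundary * dM, 0, 1),

applied iteratively (attention recomputed from the updated mask each round,
residual weights shared across rounds by default).  Where A_boundary = 0 the
coarse prediction passes through exactly; positive residuals can only raise
the mask (false-negative repair), negative only lower it (false-positive
suppression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .nn import Conv2d, Module, Parameter, Tensor, concat, upsample2

__all__ = ["EdgeMaps", "RefinementState", "sobel_edges", "SemanticEdgeHead",
           "EdgeFusion", "BoundaryAttention", "apply_refinement", "DBARRefiner"]


@dataclass
class EdgeMaps:
    E_sobel: np.ndarray
    E_sem: Tensor
    E_boundary: Tensor


@dataclass
class RefinementState:
    M_coarse: Tensor
    A_boundary: Tensor
    M_refined: Tensor
    iterations: int


def sobel_edges(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) with the standard 3x3 Sobel
    kernels and reflect padding.  Accepts (H, W) or (B, 1, H, W)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        gy = ndi.sobel(img, axis=0, mode="reflect")
        gx = ndi.sobel(img, axis=1, mode="reflect")
        return np.sqrt(gx * gx + gy * gy)
    out = np.empty_like(img)
    for b in range(img.shape[0]):
        out[b, 0] = sobel_edges(img[b, 0])
    return out


class SemanticEdgeHead(Module):
    """Small conv stack on high-level features -> single-channel sigmoid map
    at the input-image grid (features upsampled as needed)."""

    def __init__(self, c_in: int, rng, upsamples: int = 3, hidden: int = 8):
        self.conv1 = Conv2d(c_in, hidden, 3, rng)
        self.conv2 = Conv2d(hidden, 1, 3, rng)
        self.upsamples = upsamples

    def forward(self, features: Tensor) -> Tensor:
        z = self.conv2(self.conv1(features).relu())
        for _ in range(self.upsamples):
            z = upsample2(z)
        return z.sigmoid()


class EdgeFusion(Module):
    """E_boundary = sigmoid(w1 * normalize(E_sobel) + w2 * E_sem + b); the
    Sobel map is normalized by its per-image maximum for contrast
    invariance."""

    def __init__(self):
        self.w1 = Parameter(np.ones(()))
        self.w2 = Parameter(np.ones(()))
        self.b = Parameter(np.zeros(()))

    def forward(self, e_sobel: np.ndarray, e_sem: Tensor) -> Tensor:
        arr = np.asarray(e_sobel, dtype=np.float32)
        peak = arr.max(axis=(-1, -2), keepdims=True)
        norm = Tensor(arr / np.maximum(peak, 1e-8))
        return (self.w1 * norm + self.w2 * e_sem + self.b).sigmoid()


class BoundaryAttention(Module):
    """Cascaded 3x3 convolutions over [U, ambiguity, E_boundary] -> (0,1)."""

    def __init__(self, rng, hidden: int = 8):
        self.conv1 = Conv2d(3, hidden, 3, rng)
        self.conv2 = Conv2d(hidden, 1, 3, rng)

    @staticmethod
    def ambiguity(m_coarse: Tensor) -> Tensor:
        """1 - 2|M - 0.5|: maximal at p = 0.5, zero at p in {0, 1}."""
        return 1.0 - 2.0 * (m_coarse - 0.5).abs()

    def forward(self, u_map: Tensor, m_coarse: Tensor, e_boundary: Tensor) -> Tensor:
        amb = self.ambiguity(m_coarse)
        z = self.conv2(self.conv1(concat([u_map, amb, e_boundary], axis=1)).relu())
        return z.sigmoid()


def apply_refinement(m: Tensor, a_boundary: Tensor, delta_m: Tensor) -> Tensor:
    """One gated residual update, clamped to the unit interval (straight-
    through gradient, so saturated pixels remain trainable)."""
    return (m + a_boundary * delta_m).clip_st(0.0, 1.0)


class DBARRefiner(Module):
    def __init__(self, c_features: int, rng, iterations: int = 2,
                 shared_weights: bool = True, hidden: int = 8,
                 delta_scale: float = 0.5):
        self.iterations = iterations
        self.edge_head: SemanticEdgeHead | None = None   # built by the model
        self.fusion = EdgeFusion()
        self.attention = BoundaryAttention(rng)
        n_blocks = 1 if shared_weights else iterations
        self.delta_conv1 = [Conv2d(c_features + 2, hidden, 3, rng) for _ in range(n_blocks)]
        self.delta_conv2 = [Conv2d(hidden, 1, 3, rng, zero_init=True) for _ in range(n_blocks)]
        self.shared_weights = shared_weights
        # bounds each per-iteration correction; tempers the saturation a raw
        # tanh residual would impose on the refined probabilities
        self.delta_scale = delta_scale

    def forward(self, m_coarse: Tensor, u_map: Tensor, e_boundary: Tensor,
                features: Tensor, iterations: int | None = None) -> RefinementState:
        iters = self.iterations if iterations is None else iterations
        if iters < 1:
            raise ValueError("iterations must be >= 1")
        m = m_coarse
        a = None
        for it in range(iters):
            a = self.attention(u_map, m, e_boundary)
            idx = 0 if self.shared_weights else it
            z = self.delta_conv1[idx](concat([features, m, a], axis=1)).relu()
            delta = self.delta_conv2[idx](z).tanh() * self.delta_scale
            m = apply_refinement(m, a, delta)
        return RefinementState(M_coarse=m_coarse, A_boundary=a, M_refined=m,
                               iterations=iters)
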