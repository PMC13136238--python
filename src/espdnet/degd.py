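"""Dirichlet evidential guided decoder.

Segmentation is cast as second-order probability estimation: at every decoder
scale an evidence head emits per-pixel logits that are mapped to Dirichlet
concentrations

    alpha_k = 1 + softplus(logit_k)  >= 1,

so the per-pixel class probability vector p ~ Dir(alpha).  Total evidence
S = sum_k alpha_k, epistemic uncertainty U = K / S in (0, 1] (U = 1 iff all
alpha_k = 1, i.e. total ignorance), and the expected class probabilities are
p_k = alpha_k / S — the mean of the Dirichlet.  Two pixels can share p = 0.5
yet differ sharply in U: a high-evidence "confident boundary" versus a
low-evidence "ambiguous region".

The decoder couples this uncertainty back into feature reconstruction:
encoder skip features are modulated multiplicatively by an evidential
attention map before fusion (``F * (1 + alpha * A)`` followed by a 1x1
channel-reduction), where A comes either from a cross-attention over the
evidential probability mask, the bottleneck semantics and the boundary edge
map (coarsest two modulated scales) or from a cheap gated MLP over
[Q_pred, K_conf = 1 - U, V_evidence] at the finest scale.  The final-scale
expected foreground probability, upsampled to the input grid, is the coarse
mask — mask and Dirichlet field agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Conv2d, GroupNorm, Module, Parameter, Tensor, avg_pool2,
                 concat, softmax, upsample2)

__all__ = [
    "DirichletField", "EvidencePyramid", "evidence_to_alpha",
    "dirichlet_uncertainty", "expected_probability", "DirichletAttention",
    "EvidenceGuidedAttention", "modulate_skip", "DEGDecoder",
]


# --------------------------------------------------------------------------
# Dirichlet algebra (works on plain arrays and on autodiff tensors)
# --------------------------------------------------------------------------

def _class_axis(x, axis):
    if axis is not None:
        return axis
    return 1 if (x.ndim >= 3) else 0


def evidence_to_alpha(logits, axis: int | None = None):
    """alpha = 1 + softplus(logits); guarantees alpha >= 1 elementwise."""
    if isinstance(logits, Tensor):
        if not np.all(np.isfinite(logits.data)):
            raise ValueError("non-finite evidence logits")
        return logits.softplus() + 1.0
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite evidence logits")
    return 1.0 + np.logaddexp(0.0, logits)


def dirichlet_uncertainty(alpha, axis: int | None = None):
    """(S, U) with S = sum_k alpha_k and U = K / S.

    High-evidence pixels (S >> K) have U -> 0; minimal evidence (all
    alpha_k = 1, S = K) gives U = 1.
    """
    if isinstance(alpha, Tensor):
        ax = _class_axis(alpha, axis)
        K = alpha.shape[ax]
        if np.any(alpha.data < 1.0 - 1e-6):
            raise ValueError("Dirichlet concentrations must satisfy alpha_k >= 1")
        S = alpha.sum(axis=ax, keepdims=True)
        return S, float(K) / S
    alpha = np.asarray(alpha, dtype=np.float64)
    ax = _class_axis(alpha, axis)
    if np.any(alpha < 1.0 - 1e-9):
        raise ValueError("Dirichlet concentrations must satisfy alpha_k >= 1")
    K = alpha.shape[ax]
    S = alpha.sum(axis=ax, keepdims=True)
    return np.squeeze(S, axis=ax), np.squeeze(K / S, axis=ax)


def expected_probability(alpha, axis: int | None = None):
    """Mean of Dir(alpha): p_k = alpha_k / S (sums to 1 over classes)."""
    if isinstance(alpha, Tensor):
        ax = _class_axis(alpha, axis)
        return alpha / alpha.sum(axis=ax, keepdims=True)
    alpha = np.asarray(alpha, dtype=np.float64)
    ax = _class_axis(alpha, axis)
    return alpha / alpha.sum(axis=ax, keepdims=True)


@dataclass
class DirichletField:
    """Per-pixel Dirichlet concentrations and derived quantities (K classes
    along axis 1 of (B, K, H, W) tensors)."""
    alpha: Tensor

    def __post_init__(self):
        self.S = self.alpha.sum(axis=1, keepdims=True)
        self.U = float(self.alpha.shape[1]) / self.S
        self.p = self.alpha / self.S

    @property
    def K(self) -> int:
        return self.alpha.shape[1]


@dataclass
class EvidencePyramid:
    """Decoder-scale Dirichlet fields, coarsest (stride 16) first."""
    fields: list
    features: list

    @property
    def uncertainty_maps(self):
        """Per-scale uncertainty maps, coarsest first (the S3 -> S0 panel)."""
        return [f.U.data[:, 0] for f in self.fields]


# --------------------------------------------------------------------------
# attention blocks
# --------------------------------------------------------------------------

class EvidenceGuidedAttention(Module):
    """Gated MLP attention over [Q_pred, K_conf, V_evidence] (per pixel).

    The final projection is zero-initialized and scaled by a learnable gate,
    so the attention starts at sigmoid(0) = 0.5 everywhere.
    """

    def __init__(self, c_value: int, rng, hidden: int = 8):
        self.mlp1 = Conv2d(2 + c_value, hidden, 1, rng)
        self.mlp2 = Conv2d(hidden, 1, 1, rng, zero_init=True)
        self.gate = Parameter(np.ones(()))

    def forward(self, q_pred: Tensor, k_conf: Tensor, v_evidence: Tensor) -> Tensor:
        if q_pred.shape[2:] != k_conf.shape[2:] or q_pred.shape[2:] != v_evidence.shape[2:]:
            raise ValueError("attention inputs must share spatial size")
        z = self.mlp2(self.mlp1(concat([q_pred, k_conf, v_evidence], axis=1)).relu())
        return (self.gate * z).sigmoid()


class DirichletAttention(Module):
    """Single-head cross-attention fusing the evidential probability mask
    (queries) with bottleneck semantics and boundary edges (keys/values);
    terminal sigmoid keeps the map in (0, 1)."""

    def __init__(self, c_ctx: int, rng, dim: int = 8):
        self.dim = dim
        self.q = Conv2d(1, dim, 1, rng, bias=False)
        self.k = Conv2d(c_ctx + 1, dim, 1, rng, bias=False)
        self.v = Conv2d(c_ctx + 1, dim, 1, rng)
        self.out = Conv2d(dim, 1, 1, rng)

    def forward(self, p_mask: Tensor, semantic: Tensor, e_boundary: Tensor) -> Tensor:
        B, _, H, W = p_mask.shape
        ctx = concat([semantic, e_boundary], axis=1)
        q = self.q(p_mask).reshape(B, self.dim, H * W).transpose(0, 2, 1)
        k = self.k(ctx).reshape(B, self.dim, H * W)
        v = self.v(ctx).reshape(B, self.dim, H * W).transpose(0, 2, 1)
        attn = softmax((q @ k) * (1.0 / np.sqrt(self.dim)), axis=-1)
        fused = (attn @ v).transpose(0, 2, 1).reshape(B, self.dim, H, W)
        return self.out(fused).sigmoid()


def modulate_skip(F_input: Tensor, A_dir: Tensor, alpha) -> Tensor:
    """Evidence-modulated skip: F * (1 + alpha * A_dir) (before the 1x1
    channel-reduction convolution that follows in the decoder)."""
    if not isinstance(alpha, Tensor):
        alpha = Tensor(np.asarray(alpha, dtype=np.float32))
    return F_input * (1.0 + alpha * A_dir)


# --------------------------------------------------------------------------
# decoder
# --------------------------------------------------------------------------

class _DecodeBlock(Module):
    def __init__(self, c_in: int, c_out: int, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.norm1 = GroupNorm(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.norm2 = GroupNorm(c_out)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(x)).relu()


class DEGDecoder(Module):
    """Four-stage decoder over the encoder pyramid and the bottleneck map.

    ``evidential=False`` swaps the per-scale Dirichlet evidence heads and
    evidential skip modulation for a plain softmax head and plain skips —
    the deterministic baseline used for calibration comparisons.
    """

    K = 2

    def __init__(self, stage_channels, c_bottleneck: int, rng,
                 evidential: bool = True, n_classes: int = 2):
        self.evidential = evidential
        self.K = n_classes
        cs = stage_channels                       # encoder widths, finest first
        dec = [max(4, c // 1) for c in cs]        # decoder widths mirror encoder
        self.dec_channels = dec
        # stage at stride 16: bottleneck (pooled) + s3 skip
        self.block3 = _DecodeBlock(c_bottleneck + cs[3], dec[3], rng)
        self.reduce2 = Conv2d(cs[2], dec[2], 1, rng)
        self.block2 = _DecodeBlock(dec[3] + dec[2], dec[2], rng)
        self.reduce1 = Conv2d(cs[1], dec[1], 1, rng)
        self.block1 = _DecodeBlock(dec[2] + dec[1], dec[1], rng)
        self.reduce0 = Conv2d(cs[0], dec[0], 1, rng)
        self.block0 = _DecodeBlock(dec[1] + dec[0], dec[0], rng)
        if evidential:
            self.heads = [Conv2d(dec[i], n_classes, 1, rng) for i in (3, 2, 1, 0)]
            self.attn2 = DirichletAttention(c_bottleneck, rng)
            self.attn1 = DirichletAttention(c_bottleneck, rng)
            self.guided0 = EvidenceGuidedAttention(dec[1], rng)
            self.skip_alphas = [Parameter(np.zeros(())) for _ in range(3)]
        else:
            self.head = Conv2d(dec[0], n_classes, 1, rng)

    # -- helpers -----------------------------------------------------------
    def _field(self, idx: int, feats: Tensor) -> DirichletField:
        logits = self.heads[idx](feats)
        return DirichletField(evidence_to_alpha(logits, axis=1))

    def forward(self, pyramid, s_final: Tensor, e_boundary: Tensor):
        """Returns (M_coarse, EvidencePyramid | softmax probability tensor,
        final-stage feature map).

        ``e_boundary`` is the fused edge map at the input grid; it is average
        pooled to each attention grid.
        """
        s0, s1, s2, s3 = pyramid.s0, pyramid.s1, pyramid.s2, pyramid.s3
        eb8 = avg_pool2(avg_pool2(avg_pool2(e_boundary)))   # stride 8
        fields, feats_list = [], []
        x = self.block3(concat([avg_pool2(s_final), s3], axis=1))
        if self.evidential:
            f3 = self._field(0, x)
            fields.append(f3)
        feats_list.append(x)

        # stride 8: cross-attention modulated skip
        x = upsample2(x)
        if self.evidential:
            p_up = upsample2(fields[-1].p[:, 1:2])
            a_dir2 = self.attn2(p_up, s_final, eb8)
            skip = self.reduce2(modulate_skip(s2, a_dir2, self.skip_alphas[0]))
        else:
            skip = self.reduce2(s2)
        x = self.block2(concat([x, skip], axis=1))
        if self.evidential:
            fields.append(self._field(1, x))
        feats_list.append(x)

        # stride 4: cross-attention at the second modulated scale
        x = upsample2(x)
        if self.evidential:
            p_up = upsample2(fields[-1].p[:, 1:2])
            a_dir1 = self.attn1(p_up, upsample2(s_final), upsample2(eb8))
            skip = self.reduce1(modulate_skip(s1, a_dir1, self.skip_alphas[1]))
        else:
            skip = self.reduce1(s1)
        x = self.block1(concat([x, skip], axis=1))
        if self.evidential:
            fields.append(self._field(2, x))
        feats_list.append(x)

        # stride 2: cheap gated-MLP evidential attention
        x_up = upsample2(x)
        if self.evidential:
            prev = fields[-1]
            q_pred = upsample2(prev.p[:, 1:2])
            k_conf = 1.0 - upsample2(prev.U)
            a_dir0 = self.guided0(q_pred, k_conf, x_up)
            skip = self.reduce0(modulate_skip(s0, a_dir0, self.skip_alphas[2]))
        else:
            skip = self.reduce0(s0)
        x = self.block0(concat([x_up, skip], axis=1))
        feats_list.append(x)

        if self.evidential:
            f0 = self._field(3, x)
            fields.append(f0)
            m_coarse = upsample2(f0.p[:, 1:2])
            return m_coarse, EvidencePyramid(fields=fields, features=feats_list), x
        probs = softmax(self.head(x), axis=1)
        m_coarse = upsample2(probs[:, 1:2])
        return m_coarse, probs, x
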