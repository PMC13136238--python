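"""ESPD-Net: hybrid-attention encoder, dual-path bottleneck, evidential
decoder and boundary-aware refiner, with ablation variants.

Variants (the ablation grid):

* ``espd_full``        — SPDF + DEGD + DBAR (the complete network)
* ``no_spdf``          — bottleneck replaced by a 1x1 residual projection
* ``no_degd``          — softmax decoder head, plain skips (SPDF + DBAR kept)
* ``no_dbar``          — refined mask = coarse mask
* ``softmax_baseline`` — plain encoder-decoder with a softmax head, no
  bottleneck fusion and no refinement; the deterministic reference for the
  calibration comparison.

For softmax variants the exported "uncertainty" map is the normalized
predictive entropy of the softmax distribution (so calibration diagnostics
remain comparable), and the confidence map is the maximum class probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dbar import DBARRefiner, EdgeMaps, SemanticEdgeHead, sobel_edges
from .degd import DEGDecoder, EvidencePyramid
from .encoder import Encoder, EncoderConfig
from .nn import Module, Tensor, no_grad, upsample2
from .spdf import SPDFBottleneck, SPDFConfig

__all__ = ["ModelConfig", "SegmentationOutput", "ESPDNet", "VARIANTS",
           "TINY_PROFILE", "FULL_PROFILE", "save_checkpoint", "load_checkpoint"]

VARIANTS = ("espd_full", "softmax_baseline", "no_dbar", "no_degd", "no_spdf")

TINY_PROFILE = dict(stage_channels=(8, 16, 32, 64))
FULL_PROFILE = dict(stage_channels=(32, 64, 128, 256))


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "espd_full"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    spdf: SPDFConfig = field(default_factory=SPDFConfig)
    bottleneck_channels: int | None = None
    dbar_iterations: int = 2
    dbar_shared_weights: bool = True
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    @property
    def use_spdf(self) -> bool:
        return self.variant not in ("no_spdf", "softmax_baseline")

    @property
    def use_degd(self) -> bool:
        return self.variant not in ("no_degd", "softmax_baseline")

    @property
    def use_dbar(self) -> bool:
        return self.variant not in ("no_dbar", "softmax_baseline")

    @classmethod
    def tiny(cls, **kw) -> "ModelConfig":
        enc = EncoderConfig(stage_channels=TINY_PROFILE["stage_channels"])
        return cls(encoder=enc, **kw)

    @classmethod
    def full(cls, **kw) -> "ModelConfig":
        enc = EncoderConfig(stage_channels=FULL_PROFILE["stage_channels"])
        return cls(encoder=enc, **kw)


@dataclass
class SegmentationOutput:
    m_coarse: Tensor                    # (B, 1, H, W) in [0, 1]
    m_refined: Tensor                   # (B, 1, H, W) in [0, 1]
    uncertainty: Tensor                 # (B, 1, H, W), final-scale map at input grid
    confidence: np.ndarray              # (B, 1, H, W) max-class probability
    evidence: EvidencePyramid | None    # None for softmax variants
    edges: EdgeMaps
    a_boundary: Tensor | None

    @property
    def uncertainty_maps(self):
        """Per-scale uncertainty maps (coarsest first) for evidential
        variants, else the single entropy map."""
        if self.evidence is not None:
            return self.evidence.uncertainty_maps
        return [self.uncertainty.data[:, 0]]


class ESPDNet(Module):
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = Encoder(config.encoder, rng)
        cs = config.encoder.stage_channels
        c_bottleneck = config.bottleneck_channels or cs[3]
        self.c_bottleneck = c_bottleneck
        self.bottleneck = SPDFBottleneck(cs[2], cs[3], c_bottleneck, config.spdf,
                                         rng, enabled=config.use_spdf)
        self.edge_head = SemanticEdgeHead(c_bottleneck, rng, upsamples=3)
        self.decoder = DEGDecoder(cs, c_bottleneck, rng,
                                  evidential=config.use_degd,
                                  n_classes=config.n_classes)
        if config.use_dbar:
            c_feat = self.decoder.dec_channels[0]
            self.refiner = DBARRefiner(c_feat, rng,
                                       iterations=config.dbar_iterations,
                                       shared_weights=config.dbar_shared_weights)

    def forward(self, image) -> SegmentationOutput:
        """image: (B, 1, H, W) array or Tensor with values in [0, 1]."""
        x = image if isinstance(image, Tensor) else Tensor(image)
        pyramid = self.encoder(x)
        dual = self.bottleneck(pyramid.s2, pyramid.s3)
        s_final = dual.s_final

        e_sobel = sobel_edges(x.data)
        e_sem = self.edge_head(s_final)
        e_boundary = self.refiner.fusion(e_sobel, e_sem) if self.config.use_dbar \
            else self._plain_fuse(e_sobel, e_sem)
        edges = EdgeMaps(E_sobel=e_sobel, E_sem=e_sem, E_boundary=e_boundary)

        m_coarse, aux, dec_feats = self.decoder(pyramid, s_final, e_boundary)

        if self.config.use_degd:
            evidence: EvidencePyramid | None = aux
            u_final = upsample2(evidence.fields[-1].U)
            conf = np.maximum(m_coarse.data, 1.0 - m_coarse.data)
        else:
            evidence = None
            p_up = m_coarse.data
            ent = -(p_up * np.log(np.clip(p_up, 1e-7, 1)) +
                    (1 - p_up) * np.log(np.clip(1 - p_up, 1e-7, 1))) / np.log(2.0)
            u_final = Tensor(ent.astype(np.float32))
            conf = np.maximum(p_up, 1.0 - p_up)

        if self.config.use_dbar:
            feats = upsample2(dec_feats)
            state = self.refiner(m_coarse, u_final, e_boundary, feats)
            m_refined, a_boundary = state.M_refined, state.A_boundary
        else:
            m_refined, a_boundary = m_coarse, None

        conf_refined = np.maximum(m_refined.data, 1.0 - m_refined.data)
        return SegmentationOutput(m_coarse=m_coarse, m_refined=m_refined,
                                  uncertainty=u_final, confidence=conf_refined,
                                  evidence=evidence, edges=edges,
                                  a_boundary=a_boundary)

    @staticmethod
    def _plain_fuse(e_sobel, e_sem):
        arr = np.asarray(e_sobel, dtype=np.float32)
        peak = arr.max(axis=(-1, -2), keepdims=True)
        return (Tensor(arr / np.maximum(peak, 1e-8)) + e_sem).sigmoid()

    def predict(self, image) -> SegmentationOutput:
        with no_grad():
            return self.forward(image)


# --------------------------------------------------------------------------
# checkpoint I/O: npz archive with an embedded JSON config header
# --------------------------------------------------------------------------

def _config_to_json(config: ModelConfig) -> str:
    d = {
        "variant": config.variant,
        "encoder": {
            "in_channels": config.encoder.in_channels,
            "stage_channels": list(config.encoder.stage_channels),
            "se_reduction": config.encoder.se_reduction,
            "cbam_kernel": config.encoder.cbam_kernel,
            "identity_gates": config.encoder.identity_gates,
        },
        "spdf": {
            "window": config.spdf.window,
            "deform_kernel": config.spdf.deform_kernel,
            "ffn_expansion": config.spdf.ffn_expansion,
            "n_heads": config.spdf.n_heads,
            "attn_dim": config.spdf.attn_dim,
        },
        "bottleneck_channels": config.bottleneck_channels,
        "dbar_iterations": config.dbar_iterations,
        "dbar_shared_weights": config.dbar_shared_weights,
        "n_classes": config.n_classes,
        "seed": config.seed,
    }
    return json.dumps(d)


def _config_from_json(s: str) -> ModelConfig:
    d = json.loads(s)
    enc = d.pop("encoder")
    enc["stage_channels"] = tuple(enc["stage_channels"])
    spdf = d.pop("spdf")
    return ModelConfig(encoder=EncoderConfig(**enc), spdf=SPDFConfig(**spdf), **d)


def save_checkpoint(model: ESPDNet, path, extra: dict | None = None):
    header = {"config": _config_to_json(model.config), "extra": json.dumps(extra or {})}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[ESPDNet, dict]:
    with np.load(path) as zf:
        header = json.loads(bytes(zf["__header__"]).decode())
        state = {k[len("param/"):]: zf[k] for k in zf.files if k.startswith("param/")}
    config = _config_from_json(header["config"])
    model = ESPDNet(config)
    model.load_state_dict(state)
    return model, json.loads(header["extra"])
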