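"""Full model assembly and ablation variants.

``EEDModel`` wires encoder → hierarchical transformer stack (with dense
purification at every layer) → feature combination → transformer encoder →
classifier / projection head.  Variants reproduce the standard ablations:

========== ==========================================================
full        everything enabled (MG-LA coarse attention, 3 branches)
no_hcmft    two-branch layers (no medium branch)
no_adip     plain global-mean log-power, no attention in purification
no_dscsfe   dense-convolution baseline encoder
no_te       combined features go straight to the MLP classifier
msa_cgb     standard multi-head softmax attention replaces MG-LA
========== ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .adip import ADIPConfig, ADIPStage
from .encoder import EncoderConfig, make_encoder
from .head import Head, HeadConfig, combine
from .hcmft import HCTLayer, MGLAConfig
from .nn import Module, Tensor, as_tensor

VARIANTS = ("full", "no_hcmft", "no_adip", "no_dscsfe", "no_te", "msa_cgb")


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    mgla: MGLAConfig = field(default_factory=MGLAConfig)
    adip: ADIPConfig = field(default_factory=ADIPConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    n_layers: int = 3
    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {VARIANTS}")
        if self.head.embed_dim != self.encoder.embed_dim:
            raise ValueError("head and encoder embed_dim must agree")
        if self.encoder.n_tokens < 2 ** self.n_layers:
            raise ValueError(
                f"{self.encoder.n_tokens} tokens cannot support "
                f"{self.n_layers} halving layers")


def desk_config(n_channels: int = 8, n_classes: int = 2,
                window_samples: int = 256, n_layers: int = 3) -> ModelConfig:
    """A reduced-width configuration for CPU-scale training runs.

    Pooling factor 16 (250 ms at 64 Hz) makes the post-ELU mean an envelope
    for every band the generator plants, so band-power features exist right
    after the depthwise temporal stage; one final-encoder layer keeps the
    desk model small.
    """
    from .adip import ADIPConfig

    enc = EncoderConfig(n_channels=n_channels, window_samples=window_samples,
                        temporal_kernel=25, depth_multiplier=4, n_filters=24,
                        pool_factor=16, patch_len=2, embed_dim=32,
                        out_expansion=2)
    head = HeadConfig(embed_dim=32, n_heads=4, n_classes=n_classes,
                      proj_dim=64, n_encoder_layers=1)
    return ModelConfig(encoder=enc, head=head, n_layers=n_layers,
                       adip=ADIPConfig(power_window=8))


class EEDModel(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 0):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        v = cfg.variant
        enc_kind = "baseline" if v == "no_dscsfe" else "dsc"
        attention = "msa" if v == "msa_cgb" else "mgla"
        use_medium = v != "no_hcmft"
        adip_cfg = (replace(cfg.adip, mode="dip") if v == "no_adip"
                    else cfg.adip)
        head_cfg = (replace(cfg.head, n_encoder_layers=0) if v == "no_te"
                    else cfg.head)
        d = cfg.encoder.embed_dim
        self.encoder = make_encoder(enc_kind, cfg.encoder, rng)
        self.layers = [HCTLayer(d, cfg.mgla, rng, attention=attention,
                                use_medium=use_medium)
                       for _ in range(cfg.n_layers)]
        self.adip_stages = [ADIPStage(d, adip_cfg, rng)
                            for _ in range(cfg.n_layers)]
        self.head = Head(head_cfg, rng)

    # ------------------------------------------------------------------ paths
    def features(self, x) -> dict:
        """Run encoder + hierarchical stack; returns the named feature maps."""
        x = as_tensor(np.asarray(x, dtype=np.float32)
                      if not isinstance(x, Tensor) else x)
        tokens = self.encoder(x)
        f = tokens
        fusions, mediums, fines = [], [], []
        for layer, stage in zip(self.layers, self.adip_stages):
            f, f_mg, f_fg = layer(f)
            mediums.append(f_mg)
            fines.append(f_fg)
            fusions.append(stage(f_mg, f_fg))
        f_concat = combine(f, fusions)
        return {"tokens": tokens, "integ": f, "fusions": fusions,
                "mediums": mediums, "fines": fines, "concat": f_concat}

    def forward(self, x) -> Tensor:
        """Class probabilities for a (N, C, T) batch."""
        feats = self.features(x)
        h = self.head.encode(feats["concat"])
        return self.head.classify(h)

    def logits(self, x) -> Tensor:
        feats = self.features(x)
        return self.head.logits(self.head.encode(feats["concat"]))

    def project(self, x) -> Tensor:
        """L2-normalized contrastive embeddings for a (N, C, T) batch."""
        feats = self.features(x)
        return self.head.project(feats["concat"])

    # ------------------------------------------------------------- parameter groups
    def encoder_parameters(self) -> list[Tensor]:
        """Representation parameters (everything before the classifier MLP),
        the group affected by the fine-tuning freeze policy."""
        params = list(self.encoder.parameters())
        for layer in self.layers:
            params.extend(layer.parameters())
        for stage in self.adip_stages:
            params.extend(stage.parameters())
        for te in self.head.encoder_layers:
            params.extend(te.parameters())
        return params

    def classifier_parameters(self) -> list[Tensor]:
        ids = {id(p) for p in self.encoder_parameters()}
        return [p for p in self.parameters() if id(p) not in ids]

    def attention_records(self) -> list[np.ndarray]:
        """ADIP attention maps captured during the last forward pass."""
        recs = []
        for stage in self.adip_stages:
            for block in (stage.medium, stage.fine):
                if block.last_attention is not None:
                    recs.append(block.last_attention)
        return recs
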