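"""Architecture and training configuration records.

The model is a U-shaped hybrid: a five-stage residual CNN encoder running next
to a three-stage windowed-attention (Swin-style) encoder, cross-attention
fusion of the paired stages, a global dual-attention bottleneck, and a
four-stage deconvolution decoder.  Resolutions follow from a stride-1 CNN stem
and four stride-2 reductions: stages sit at H, H/2, H/4, H/8, H/16, with the
attention branch entering at H/4 (the overlapping patch embed is two stride-2
convolution sets) so its three stages pair with CNN stages 3-5.

All records serialise to/from YAML; the resolution table is always derived,
never stored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .errors import ConfigError

__all__ = [
    "EncoderConfig",
    "DualAttentionConfig",
    "AblationFlags",
    "ModelConfig",
    "TrainConfig",
    "ablation_configs",
]


@dataclass
class EncoderConfig:
    """Dual-branch encoder hyperparameters.

    ``swin_depths`` counts block *pairs* per stage: each unit is one windowed
    plus one shifted-window attention block (the canonical two-block cycle).
    """

    base_width: int = 32
    cnn_channels: tuple = (32, 64, 128, 256, 512)
    swin_dims: tuple = (128, 256, 512)
    swin_depths: tuple = (1, 1, 1)
    num_heads: tuple = (4, 8, 16)
    window_size: int = 8
    mlp_ratio: float = 4.0
    rel_pos_bias: bool = True

    def __post_init__(self):
        self.cnn_channels = tuple(int(c) for c in self.cnn_channels)
        self.swin_dims = tuple(int(c) for c in self.swin_dims)
        self.swin_depths = tuple(int(c) for c in self.swin_depths)
        self.num_heads = tuple(int(c) for c in self.num_heads)
        if len(self.cnn_channels) != 5:
            raise ConfigError("cnn_channels must list 5 stage widths")
        if len(self.swin_dims) != 3 or len(self.swin_depths) != 3 or len(self.num_heads) != 3:
            raise ConfigError("swin_dims/swin_depths/num_heads must list 3 stages")
        for i in range(3):
            if self.swin_dims[i] != self.cnn_channels[i + 2]:
                raise ConfigError(
                    f"swin_dims[{i}]={self.swin_dims[i]} must equal "
                    f"cnn_channels[{i + 2}]={self.cnn_channels[i + 2]} so paired stages fuse"
                )
            if self.swin_depths[i] < 1:
                raise ConfigError(f"swin_depths[{i}] must be >= 1")
            if self.swin_dims[i] % self.num_heads[i] != 0:
                raise ConfigError(f"swin_dims[{i}] not divisible by num_heads[{i}]")

    def stage_extents(self, image_size: int) -> dict:
        """Derived resolution table for a square input of side ``image_size``."""
        s = image_size
        return {
            "cnn": (s, s // 2, s // 4, s // 8, s // 16),
            "swin": (s // 4, s // 8, s // 16),
        }


@dataclass
class DualAttentionConfig:
    """Bottleneck dual-attention hyperparameters."""

    embed_dim: int = 512
    num_blocks: int = 2
    heads: int = 16
    mlp_ratio: float = 4.0
    block_order: str = "GSA_then_GCA"
    gca_scale: str = "sqrt"  # "sqrt" -> 1/sqrt(C); "linear" -> 1/C

    def __post_init__(self):
        if self.embed_dim % self.heads != 0:
            raise ConfigError("embed_dim must be divisible by heads")
        if self.num_blocks < 1:
            raise ConfigError("num_blocks must be >= 1")
        if self.block_order not in ("GSA_then_GCA", "GCA_then_GSA"):
            raise ConfigError(f"unknown block_order {self.block_order!r}")
        if self.gca_scale not in ("sqrt", "linear"):
            raise ConfigError(f"unknown gca_scale {self.gca_scale!r}")


@dataclass
class AblationFlags:
    """Component toggles mirroring the ablation matrix."""

    use_swin_branch: bool = True
    use_cnn_branch: bool = True
    use_caf: bool = True
    use_gsa: bool = True
    use_gca: bool = True

    def __post_init__(self):
        if not (self.use_swin_branch or self.use_cnn_branch):
            raise ConfigError("at least one encoder branch must be enabled")


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    bottleneck: DualAttentionConfig = field(default_factory=DualAttentionConfig)
    decoder_channels: tuple = (256, 128, 64, 32)
    ablation: AblationFlags = field(default_factory=AblationFlags)
    threshold: float = 0.5

    def __post_init__(self):
        self.decoder_channels = tuple(int(c) for c in self.decoder_channels)
        if len(self.decoder_channels) != 4:
            raise ConfigError("decoder_channels must list 4 stage widths")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigError("threshold must lie strictly between 0 and 1")

    # ------------------------------------------------------------------ presets
    @staticmethod
    def base() -> "ModelConfig":
        return ModelConfig()

    @staticmethod
    def tiny() -> "ModelConfig":
        """Desk-scale preset trainable on a single CPU (base_width 8, window 4)."""
        enc = EncoderConfig(
            base_width=8,
            cnn_channels=(8, 16, 32, 64, 128),
            swin_dims=(32, 64, 128),
            swin_depths=(1, 1, 1),
            num_heads=(4, 8, 16),
            window_size=4,
        )
        bott = DualAttentionConfig(embed_dim=128, num_blocks=2, heads=8, mlp_ratio=2.0)
        return ModelConfig(encoder=enc, bottleneck=bott, decoder_channels=(64, 32, 16, 8))

    def with_ablation(self, **flags) -> "ModelConfig":
        return replace(self, ablation=replace(self.ablation, **flags))

    # --------------------------------------------------------------------- yaml
    def to_yaml(self) -> str:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj

        return yaml.safe_dump(listify(asdict(self)), sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "ModelConfig":
        raw = yaml.safe_load(text)
        return ModelConfig(
            encoder=EncoderConfig(**raw["encoder"]),
            bottleneck=DualAttentionConfig(**raw["bottleneck"]),
            decoder_channels=tuple(raw["decoder_channels"]),
            ablation=AblationFlags(**raw["ablation"]),
            threshold=raw.get("threshold", 0.5),
        )


@dataclass
class TrainConfig:
    """Training recipe: Adam (beta1 0.9), cosine-annealed learning rate."""

    epochs: int = 200
    batch_size: int = 8
    lr: float = 1e-4
    min_lr: float = 1e-5
    input_size: int = 256
    seed: int = 0
    augment: bool = False

    def __post_init__(self):
        if self.min_lr > self.lr:
            raise ConfigError("min_lr must not exceed lr")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.input_size % 32 != 0:
            raise ConfigError("input_size must be divisible by 32")


def ablation_configs(base: ModelConfig | None = None) -> dict:
    """The seven configurations of the component-ablation matrix.

    Rows: each single branch alone, both branches with plain concatenation
    fusion, cross-attention fusion without the bottleneck attentions, fusion
    with only one of the two bottleneck attentions, and the full model.
    """
    cfg = base if base is not None else ModelConfig.tiny()
    off = dict(use_caf=False, use_gsa=False, use_gca=False)
    return {
        "swin_only": cfg.with_ablation(use_cnn_branch=False, **off),
        "cnn_only": cfg.with_ablation(use_swin_branch=False, **off),
        "dual_concat": cfg.with_ablation(**off),
        "dual_caf": cfg.with_ablation(use_gsa=False, use_gca=False),
        "dual_caf_gsa": cfg.with_ablation(use_gca=False),
        "dual_caf_gca": cfg.with_ablation(use_gsa=False),
        "full": cfg.with_ablation(),
    }
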