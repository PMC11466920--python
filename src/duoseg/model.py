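"""Decoder and full U-shaped model assembly, including the ablation matrix.

The decoder has four stages.  Each stage doubles the spatial extent with a
kernel-2 stride-2 deconvolution, concatenates a skip map of matching
resolution, and refines with a residual convolution block.  With both encoder
branches active the skip wiring is:

    stage 1: bottleneck (H/16) -> H/8,  skip = fusion of stage-2 pair
    stage 2: H/8  -> H/4,               skip = fusion of stage-1 pair
    stage 3: H/4  -> H/2,               skip = CNN stage 2
    stage 4: H/2  -> H,                 skip = CNN stage 1

(the deepest fusion output feeds the bottleneck, not a skip).  A 1x1
convolution and a sigmoid produce the per-pixel lesion probability map.

Ablation flags prune components: either branch can run alone (a single-branch
model keeps a runnable decoder — the attention-only variant derives its two
high-resolution skips from lightweight convolutional stems), cross-attention
fusion can be replaced by concatenation + 1x1 convolution, and the two
bottleneck attentions can be disabled independently.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .bottleneck import Bottleneck
from .config import ModelConfig
from .encoders import DualEncoder, ResidualConvBlock, validate_image
from .errors import ConfigError, ShapeError
from .fusion import ConcatFusion, CrossAttentionFusion
from .nn import Tensor

__all__ = ["DecoderStage", "SegmentationModel", "build_model"]


class DecoderStage(nn.Module):
    """Deconvolution upsampling, skip concatenation, residual refinement."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int):
        super().__init__()
        self.up = nn.ConvTranspose2d(in_ch, out_ch, kernel=2, stride=2)
        self.block = ResidualConvBlock(out_ch + skip_ch, out_ch, stride=1)

    def forward(self, low_res: Tensor, skip: Tensor) -> Tensor:
        up = self.up(low_res)
        if up.shape[2:] != skip.shape[2:]:
            raise ShapeError(
                f"upsampled extent {up.shape[2:]} does not match skip {skip.shape[2:]}"
            )
        return self.block(nn.concat([up, skip], axis=1))


class _ConvStem(nn.Module):
    """Conv-BN-ReLU stem supplying high-resolution skips to single-branch models."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return nn.relu(self.bn(self.conv(x)))


class SegmentationModel(nn.Module):
    """U-shaped dual-branch segmentation network with component toggles."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        enc, ab = cfg.encoder, cfg.ablation
        ch = enc.cnn_channels
        dims = enc.swin_dims
        dc = cfg.decoder_channels
        self.dual = ab.use_swin_branch and ab.use_cnn_branch

        self.encoder = DualEncoder(enc, use_swin=ab.use_swin_branch, use_cnn=ab.use_cnn_branch)

        if self.dual:
            fusion_cls = (
                (lambda d, h: CrossAttentionFusion(d, h))
                if ab.use_caf
                else (lambda d, h: ConcatFusion(d))
            )
            self.fusions = nn.ModuleList(
                fusion_cls(dims[i], enc.num_heads[i]) for i in range(3)
            )
            bott_in = 3 * dims[2]
            skips = [dims[1], dims[0], ch[1], ch[0]]
        elif ab.use_swin_branch:
            bott_in = dims[2]
            skips = [dims[1], dims[0], ch[1], ch[0]]
            self.stem_full = _ConvStem(1, ch[0], stride=1)
            self.stem_half = _ConvStem(ch[0], ch[1], stride=2)
        else:
            bott_in = ch[4]
            skips = [ch[3], ch[2], ch[1], ch[0]]

        self.bottleneck = Bottleneck(bott_in, cfg.bottleneck, ab.use_gsa, ab.use_gca)

        stage_in = [cfg.bottleneck.embed_dim, dc[0], dc[1], dc[2]]
        try:
            self.decoder = nn.ModuleList(
                DecoderStage(stage_in[s], skips[s], dc[s]) for s in range(4)
            )
        except ValueError as exc:  # pragma: no cover - defensive
            raise ConfigError(f"inconsistent decoder channel arithmetic: {exc}") from exc
        self.head = nn.Conv2d(dc[3], 1, 1)

    # ------------------------------------------------------------------ forward
    def forward(self, image: Tensor) -> Tensor:
        validate_image(image)
        outs = self.encoder(image)

        if self.dual:
            fused = [
                self.fusions[i](outs.swin_feats[i], outs.cnn_feats[i + 2]) for i in range(3)
            ]
            bott_maps = [outs.swin_feats[2], outs.cnn_feats[4], fused[2]]
            skips = [fused[1], fused[0], outs.cnn_feats[1], outs.cnn_feats[0]]
        elif self.cfg.ablation.use_swin_branch:
            bott_maps = [outs.swin_feats[2]]
            full = self.stem_full(image)
            skips = [outs.swin_feats[1], outs.swin_feats[0], self.stem_half(full), full]
        else:
            bott_maps = [outs.cnn_feats[4]]
            skips = [outs.cnn_feats[3], outs.cnn_feats[2], outs.cnn_feats[1], outs.cnn_feats[0]]

        x = self.bottleneck(bott_maps)
        for stage, skip in zip(self.decoder, skips):
            x = stage(x, skip)
        return nn.sigmoid(self.head(x))

    def predict_mask(self, image: Tensor) -> np.ndarray:
        """Binarise the probability map; ties at the threshold go to background."""
        with nn.no_grad():
            prob = self.forward(image)
        return (prob.data > self.cfg.threshold).astype(np.uint8)


def build_model(cfg: ModelConfig, seed: int | None = None) -> SegmentationModel:
    """Construct a model; with ``seed`` the weights are reproducible."""
    if seed is not None:
        nn.seed_all(seed)
    return SegmentationModel(cfg)
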