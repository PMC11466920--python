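"""Global dual-attention bottleneck and analytic complexity formulas.

The deepest maps of the attention branch, the CNN branch, and the last fusion
module are concatenated channel-wise, linearly embedded (patch size 1 — the
grid already sits at H/16), and passed through stacked dual-attention blocks.
Each block holds two transformer sub-blocks:

* **GSA** (global spatial attention) — standard multi-head self-attention over
  the N spatial tokens: ``softmax(Q K^T / sqrt(d_head)) V``.
* **GCA** (global channel attention) — attention over the C channels of the
  transposed token matrix: ``(softmax(Q^T K / sqrt(C)) V^T)^T``, producing a
  CxC row-stochastic mixing matrix; single-head, with the 1/sqrt(C) scale
  switchable to 1/C.

Per token count N = h*w and width C, the multiplication counts are

    window attention : 4 h w C^2 + 2 M^2 h w C
    GSA              : 4 h w C^2 + 2 (h w)^2 C
    GCA              : 2 h w C^2 + 2 (h w)^2 C

so channel attention is always cheaper than spatial attention by exactly
2 h w C^2 multiplications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import DualAttentionConfig
from .encoders import map_to_tokens, tokens_to_map
from .errors import ShapeError
from .nn import Tensor
from .nn.functional import matmul, softmax

__all__ = [
    "GlobalSpatialAttention",
    "GlobalChannelAttention",
    "DualAttentionBlock",
    "Bottleneck",
    "flops_wmsa",
    "flops_gsa",
    "flops_gca",
    "ComplexityReport",
    "complexity_report",
]


class GlobalSpatialAttention(nn.Module):
    """Multi-head self-attention over all spatial tokens."""

    def __init__(self, dim: int, heads: int):
        super().__init__()
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim**-0.5
        self.q = nn.Linear(dim, dim)
        self.k = nn.Linear(dim, dim)
        self.v = nn.Linear(dim, dim)
        self.proj = nn.Linear(dim, dim)
        self.last_attn: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        b, n, _ = x.shape
        return x.reshape(b, n, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, tokens: Tensor) -> Tensor:
        b, n, c = tokens.shape
        q, k, v = (self._split(p(tokens)) for p in (self.q, self.k, self.v))
        attn = softmax(matmul(q, k.swapaxes(-1, -2)) * self.scale, axis=-1)
        self.last_attn = attn.data
        out = matmul(attn, v).transpose(0, 2, 1, 3).reshape(b, n, c)
        return self.proj(out)


class GlobalChannelAttention(nn.Module):
    """Attention over the channel axis of transposed tokens (CxC mixing)."""

    def __init__(self, dim: int, scale: str = "sqrt"):
        super().__init__()
        self.q = nn.Linear(dim, dim)
        self.k = nn.Linear(dim, dim)
        self.v = nn.Linear(dim, dim)
        self.proj = nn.Linear(dim, dim)
        self.scale_mode = scale
        self.last_attn: np.ndarray | None = None

    def forward(self, tokens: Tensor) -> Tensor:
        b, n, c = tokens.shape
        scale = c**-0.5 if self.scale_mode == "sqrt" else 1.0 / c
        q = self.q(tokens)  # B,N,C
        k = self.k(tokens)
        v = self.v(tokens)
        attn = softmax(matmul(q.swapaxes(-1, -2), k) * scale, axis=-1)  # B,C,C
        self.last_attn = attn.data
        out = matmul(attn, v.swapaxes(-1, -2))  # B,C,N
        return self.proj(out.swapaxes(-1, -2))


class _SubBlock(nn.Module):
    """LayerNorm-residual wrapper: x + op(LN(x)); x + MLP(LN(x))."""

    def __init__(self, dim: int, op: nn.Module, mlp_ratio: float):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.op = op
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = nn.Mlp(dim, int(dim * mlp_ratio))

    def forward(self, tokens: Tensor) -> Tensor:
        x = tokens + self.op(self.norm1(tokens))
        return x + self.mlp(self.norm2(x))


class DualAttentionBlock(nn.Module):
    """A GSA sub-block and a GCA sub-block in configurable order."""

    def __init__(self, cfg: DualAttentionConfig, use_gsa: bool = True, use_gca: bool = True):
        super().__init__()
        self.order = cfg.block_order
        self.gsa = (
            _SubBlock(cfg.embed_dim, GlobalSpatialAttention(cfg.embed_dim, cfg.heads), cfg.mlp_ratio)
            if use_gsa
            else None
        )
        self.gca = (
            _SubBlock(cfg.embed_dim, GlobalChannelAttention(cfg.embed_dim, cfg.gca_scale), cfg.mlp_ratio)
            if use_gca
            else None
        )

    def forward(self, tokens: Tensor) -> Tensor:
        first, second = (self.gsa, self.gca) if self.order == "GSA_then_GCA" else (self.gca, self.gsa)
        for sub in (first, second):
            if sub is not None:
                tokens = sub(tokens)
        return tokens


class Bottleneck(nn.Module):
    """Concatenation of the deepest maps, patch-1 embedding, dual-attention stack."""

    def __init__(self, in_channels: int, cfg: DualAttentionConfig, use_gsa: bool = True, use_gca: bool = True):
        super().__init__()
        self.cfg = cfg
        self.embed = nn.Linear(in_channels, cfg.embed_dim)
        self.norm = nn.LayerNorm(cfg.embed_dim)
        self.blocks = nn.ModuleList(
            DualAttentionBlock(cfg, use_gsa, use_gca) for _ in range(cfg.num_blocks)
        )

    def embed_tokens(self, maps: list) -> Tensor:
        grid = maps[0].shape[2:]
        for m in maps[1:]:
            if m.shape[2:] != grid:
                raise ShapeError(f"bottleneck maps disagree in extent: {m.shape[2:]} vs {grid}")
        stacked = nn.concat(maps, axis=1) if len(maps) > 1 else maps[0]
        return self.norm(self.embed(map_to_tokens(stacked)))

    def forward(self, maps: list) -> Tensor:
        grid = maps[0].shape[2:]
        tokens = self.embed_tokens(maps)
        for block in self.blocks:
            tokens = block(tokens)
        return tokens_to_map(tokens, grid)


# ----------------------------------------------------------------- complexity
def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if int(value) != value or value <= 0:
            raise ValueError(f"{name} must be a positive integer, got {value}")


def flops_wmsa(h: int, w: int, c: int, m: int) -> int:
    """Multiplications of window attention on an (h,w,C) map with window M."""
    _check_positive(h=h, w=w, c=c, m=m)
    return 4 * h * w * c**2 + 2 * m**2 * h * w * c


def flops_gsa(h: int, w: int, c: int) -> int:
    """Multiplications of global spatial attention (4 projections + 2 attention matmuls)."""
    _check_positive(h=h, w=w, c=c)
    return 4 * h * w * c**2 + 2 * (h * w) ** 2 * c


def flops_gca(h: int, w: int, c: int) -> int:
    """Multiplications of global channel attention; cheaper than GSA by 2hwC^2."""
    _check_positive(h=h, w=w, c=c)
    return 2 * h * w * c**2 + 2 * (h * w) ** 2 * c


@dataclass
class ComplexityReport:
    h: int
    w: int
    channels: int
    window: int
    flops_wmsa: int
    flops_gsa: int
    flops_gca: int


def complexity_report(h: int, w: int, channels: int, window: int) -> ComplexityReport:
    return ComplexityReport(
        h=h,
        w=w,
        channels=channels,
        window=window,
        flops_wmsa=flops_wmsa(h, w, channels, window),
        flops_gsa=flops_gsa(h, w, channels),
        flops_gca=flops_gca(h, w, channels),
    )
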