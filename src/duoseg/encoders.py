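"""Dual-branch encoder: windowed-attention branch + residual CNN branch.

The CNN branch has five residual stages (a stride-1 stem, then four stride-2
reductions: H, H/2, H/4, H/8, H/16).  The attention branch tokenises the image
with an overlapping patch embedding (two sets of stride-2 + stride-1 3x3
convolutions with GELU and token-wise LayerNorm) landing at H/4, then runs
three stages of window multi-head self-attention.  Each stage is a sequence of
W-MSA/SW-MSA block pairs:

    z_hat = W-MSA(LN(z)) + z
    z     = MLP(LN(z_hat)) + z_hat

followed by the shifted-window twin, where the token grid is cyclically rolled
by floor(M/2) and attention between wrapped-around regions is masked out.
Between stages, a 3x3 stride-2 convolution halves the grid and doubles the
width (in place of patch merging), so attention stage i shares its resolution
with CNN stage i+2 and the two branches can be fused stage-by-stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import EncoderConfig
from .errors import ShapeError
from .nn import Tensor
from .nn.functional import matmul, softmax

__all__ = [
    "validate_image",
    "tokens_to_map",
    "map_to_tokens",
    "window_partition",
    "window_reverse",
    "WindowAttention",
    "SwinBlockPair",
    "PatchEmbed",
    "ConvDownsample",
    "ResidualConvBlock",
    "EncoderOutputs",
    "DualEncoder",
]

NEG_INF = -1e9


def validate_image(image: Tensor, divisor: int = 32) -> None:
    """Check the (B,1,H,W) contract: square extent divisible by ``divisor``."""
    if image.ndim != 4:
        raise ShapeError(f"image must be 4-D (B,1,H,W), got {image.ndim}-D")
    b, c, h, w = image.shape
    if c != 1:
        raise ShapeError(f"image must have 1 channel, got {c}")
    if h != w:
        raise ShapeError(f"image must be square, got height {h} != width {w}")
    if h % divisor != 0:
        raise ShapeError(f"image side {h} not divisible by {divisor}")
    if not np.isfinite(image.data).all():
        raise ShapeError("image contains non-finite values")


# ------------------------------------------------------------- token plumbing
def map_to_tokens(fmap: Tensor) -> Tensor:
    """(B,C,H,W) -> (B, H*W, C) in row-major raster order."""
    b, c, h, w = fmap.shape
    return fmap.reshape(b, c, h * w).swapaxes(1, 2)


def tokens_to_map(tokens: Tensor, grid: tuple) -> Tensor:
    """(B, H*W, C) -> (B,C,H,W); inverse of :func:`map_to_tokens`."""
    b, n, c = tokens.shape
    h, w = grid
    if n != h * w:
        raise ShapeError(f"token count {n} does not match grid {h}x{w}")
    return tokens.swapaxes(1, 2).reshape(b, c, h, w)


def window_partition(fmap: Tensor, window: int) -> Tensor:
    """Split (B,C,H,W) into non-overlapping MxM windows -> (B*nW, M*M, C)."""
    b, c, h, w = fmap.shape
    if h % window or w % window:
        raise ShapeError(f"spatial extent ({h},{w}) not divisible by window {window}")
    x = fmap.transpose(0, 2, 3, 1)  # B,H,W,C
    x = x.reshape(b, h // window, window, w // window, window, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (h // window) * (w // window), window * window, c)


def window_reverse(windows: Tensor, window: int, grid: tuple) -> Tensor:
    """Exact inverse of :func:`window_partition`."""
    h, w = grid
    nw = (h // window) * (w // window)
    b = windows.shape[0] // nw
    c = windows.shape[2]
    x = windows.reshape(b, h // window, w // window, window, window, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    x = x.reshape(b, h, w, c)
    return x.transpose(0, 3, 1, 2)


def _relative_position_index(window: int) -> np.ndarray:
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]  # 2, N, N
    rel = rel + window - 1
    return rel[0] * (2 * window - 1) + rel[1]  # N, N


def shifted_window_mask(h: int, w: int, window: int, shift: int) -> np.ndarray:
    """Additive attention mask (nW, M^2, M^2) for the shifted-window pass.

    Token positions that end up in the same window after the cyclic roll but
    originate from non-adjacent image regions must not attend to each other.
    """
    img = np.zeros((h, w))
    cnt = 0
    for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
        for ws in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
            img[hs, ws] = cnt
            cnt += 1
    win = (
        img.reshape(h // window, window, w // window, window)
        .transpose(0, 2, 1, 3)
        .reshape(-1, window * window)
    )
    diff = win[:, None, :] - win[:, :, None]
    return np.where(diff != 0, NEG_INF, 0.0)


class WindowAttention(nn.Module):
    """Multi-head self-attention inside MxM windows with relative position bias."""

    def __init__(self, dim: int, heads: int, window: int, rel_pos_bias: bool = True):
        super().__init__()
        self.dim = dim
        self.heads = heads
        self.window = window
        self.head_dim = dim // heads
        self.scale = self.head_dim**-0.5
        self.qkv = nn.Linear(dim, 3 * dim)
        self.proj = nn.Linear(dim, dim)
        self.rel_pos_bias = rel_pos_bias
        if rel_pos_bias:
            from .nn import init

            self.bias_table = nn.Parameter(
                init.trunc_normal(((2 * window - 1) ** 2, heads))
            )
            self.register_buffer("bias_index", _relative_position_index(window).astype(float))
        self.last_attn: np.ndarray | None = None

    def forward(self, windows: Tensor, mask: np.ndarray | None = None) -> Tensor:
        bw, n, c = windows.shape
        qkv = self.qkv(windows).reshape(bw, n, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # 3, Bw, heads, N, dh
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = matmul(q, k.swapaxes(-1, -2)) * self.scale
        if self.rel_pos_bias:
            idx = self.bias_index.astype(int).reshape(-1)
            bias = self.bias_table[idx].reshape(n, n, self.heads).transpose(2, 0, 1)
            attn = attn + bias
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(bw // nw, nw, self.heads, n, n) + Tensor(
                mask[None, :, None, :, :]
            )
            attn = attn.reshape(bw, self.heads, n, n)
        attn = softmax(attn, axis=-1)
        self.last_attn = attn.data
        out = matmul(attn, v)  # Bw, heads, N, dh
        out = out.transpose(0, 2, 1, 3).reshape(bw, n, c)
        return self.proj(out)


class SwinBlockPair(nn.Module):
    """One W-MSA block followed by one SW-MSA block, each with a residual MLP."""

    def __init__(self, dim: int, heads: int, window: int, mlp_ratio: float = 4.0, rel_pos_bias: bool = True):
        super().__init__()
        self.window = window
        hidden = int(dim * mlp_ratio)
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window, rel_pos_bias)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp1 = nn.Mlp(dim, hidden)
        self.norm3 = nn.LayerNorm(dim)
        self.attn_shifted = WindowAttention(dim, heads, window, rel_pos_bias)
        self.norm4 = nn.LayerNorm(dim)
        self.mlp2 = nn.Mlp(dim, hidden)

    def _attend(self, tokens: Tensor, grid: tuple, attn: WindowAttention, shift: int) -> Tensor:
        h, w = grid
        b, n, c = tokens.shape
        x = tokens.reshape(b, h, w, c)
        mask = None
        if shift:
            x = x.roll((-shift, -shift), axis=(1, 2))
            mask = shifted_window_mask(h, w, self.window, shift)
        x = x.transpose(0, 3, 1, 2)  # B,C,H,W
        windows = window_partition(x, self.window)
        windows = attn(windows, mask=mask)
        x = window_reverse(windows, self.window, grid)
        x = x.transpose(0, 2, 3, 1)
        if shift:
            x = x.roll((shift, shift), axis=(1, 2))
        return x.reshape(b, n, c)

    def forward(self, tokens: Tensor, grid: tuple) -> Tensor:
        h, w = grid
        if h % self.window or w % self.window:
            raise ShapeError(f"grid ({h},{w}) not divisible by window {self.window}")
        # shift is inactive when a single window covers the whole grid
        shift = self.window // 2 if min(h, w) > self.window else 0

        x = tokens + self._attend(self.norm1(tokens), grid, self.attn, 0)
        x = x + self.mlp1(self.norm2(x))
        x = x + self._attend(self.norm3(x), grid, self.attn_shifted, shift)
        x = x + self.mlp2(self.norm4(x))
        return x


class PatchEmbed(nn.Module):
    """Overlapping patch embedding: two (stride-2 conv, stride-1 conv, GELU, LN) sets.

    Adjacent patches share pixels because the 3x3 kernels exceed the stride,
    which preserves local neighbourhood structure that disjoint patch
    tokenisation would sever.  Output lands at H/4 with ``dim`` channels.
    """

    def __init__(self, dim: int, in_ch: int = 1):
        super().__init__()
        mid = max(dim // 2, 1)
        self.conv1a = nn.Conv2d(in_ch, mid, 3, stride=2, padding=1)
        self.conv1b = nn.Conv2d(mid, mid, 3, stride=1, padding=1)
        self.norm1 = nn.LayerNorm(mid)
        self.conv2a = nn.Conv2d(mid, dim, 3, stride=2, padding=1)
        self.conv2b = nn.Conv2d(dim, dim, 3, stride=1, padding=1)
        self.norm2 = nn.LayerNorm(dim)

    @staticmethod
    def _token_norm(fmap: Tensor, norm: nn.LayerNorm) -> Tensor:
        b, c, h, w = fmap.shape
        return tokens_to_map(norm(map_to_tokens(fmap)), (h, w))

    def forward(self, image: Tensor) -> Tensor:
        b, c, h, w = image.shape
        if h != w:
            raise ShapeError(f"patch embed needs a square input, got {h}x{w}")
        if h % 4 != 0:
            raise ShapeError(f"image side {h} not divisible by 4 (two stride-2 stages)")
        x = nn.gelu(self.conv1b(self.conv1a(image)))
        x = self._token_norm(x, self.norm1)
        x = nn.gelu(self.conv2b(self.conv2a(x)))
        return self._token_norm(x, self.norm2)


class ConvDownsample(nn.Module):
    """3x3 stride-2 convolution halving the grid (in place of patch merging)."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, stride=2, padding=1)

    def forward(self, fmap: Tensor) -> Tensor:
        h, w = fmap.shape[2:]
        if h % 2 or w % 2:
            raise ShapeError(f"cannot halve odd extent ({h},{w})")
        return self.conv(fmap)


class ResidualConvBlock(nn.Module):
    """conv-BN-ReLU-conv-BN with a projected shortcut, ReLU after the sum."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, stride=1, padding=1)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if in_ch != out_ch or stride != 1:
            self.short_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride)
            self.short_bn = nn.BatchNorm2d(out_ch)
        else:
            self.short_conv = None

    def forward(self, x: Tensor) -> Tensor:
        main = self.bn2(self.conv2(nn.relu(self.bn1(self.conv1(x)))))
        short = self.short_bn(self.short_conv(x)) if self.short_conv is not None else x
        return nn.relu(main + short)

    @staticmethod
    def param_count(in_ch: int, out_ch: int, stride: int = 1) -> int:
        """Closed-form parameter count (convs + biases + batch-norm affines)."""
        n = in_ch * out_ch * 9 + out_ch + 2 * out_ch  # conv1 + bn1
        n += out_ch * out_ch * 9 + out_ch + 2 * out_ch  # conv2 + bn2
        if in_ch != out_ch or stride != 1:
            n += in_ch * out_ch + out_ch + 2 * out_ch  # 1x1 shortcut + bn
        return n


@dataclass
class EncoderOutputs:
    """All stage maps of both branches; paired stages share spatial extent."""

    cnn_feats: list | None
    swin_feats: list | None


class DualEncoder(nn.Module):
    """Runs the CNN and attention branches in lockstep over the joint stages."""

    def __init__(self, cfg: EncoderConfig, in_ch: int = 1, use_swin: bool = True, use_cnn: bool = True):
        super().__init__()
        self.cfg = cfg
        self.use_swin = use_swin
        self.use_cnn = use_cnn
        ch = cfg.cnn_channels
        if use_cnn:
            self.cnn_stages = nn.ModuleList(
                [ResidualConvBlock(in_ch, ch[0], stride=1)]
                + [ResidualConvBlock(ch[i - 1], ch[i], stride=2) for i in range(1, 5)]
            )
        if use_swin:
            self.patch_embed = PatchEmbed(cfg.swin_dims[0], in_ch=in_ch)
            self.swin_stages = nn.ModuleList(
                nn.ModuleList(
                    SwinBlockPair(
                        cfg.swin_dims[i],
                        cfg.num_heads[i],
                        cfg.window_size,
                        cfg.mlp_ratio,
                        cfg.rel_pos_bias,
                    )
                    for _ in range(cfg.swin_depths[i])
                )
                for i in range(3)
            )
            self.downsamples = nn.ModuleList(
                ConvDownsample(cfg.swin_dims[i], cfg.swin_dims[i + 1]) for i in range(2)
            )

    def forward(self, image: Tensor) -> EncoderOutputs:
        validate_image(image)
        cnn_feats = None
        if self.use_cnn:
            cnn_feats = []
            x = image
            for stage in self.cnn_stages:
                x = stage(x)
                cnn_feats.append(x)
        swin_feats = None
        if self.use_swin:
            swin_feats = []
            fmap = self.patch_embed(image)
            for i in range(3):
                if i > 0:
                    fmap = self.downsamples[i - 1](fmap)
                grid = fmap.shape[2:]
                tokens = map_to_tokens(fmap)
                for block in self.swin_stages[i]:
                    tokens = block(tokens, grid)
                fmap = tokens_to_map(tokens, grid)
                swin_feats.append(fmap)
        return EncoderOutputs(cnn_feats=cnn_feats, swin_feats=swin_feats)
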