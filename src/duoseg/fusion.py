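"""Cross-attention fusion of paired attention-branch / CNN-branch stage maps.

For a joint stage, the attention branch yields a globally-contexted map F and
the CNN branch a locally-detailed map G at the same resolution.  Both are
flattened to token sequences and fused bidirectionally:

    A1 = softmax(Q_F K_G^T / sqrt(d)) V_G     (F queries attend to G)
    A2 = softmax(Q_G K_F^T / sqrt(d)) V_F     (G queries attend to F)

The two attended maps are concatenated channel-wise and linearly projected to
the stage's skip width.  Attention is exact over all N = H*W tokens (the
stages involved sit at H/4 and below, so N stays small); an optional stride-2
key/value pooling is available for large inputs.  No positional encoding is
added, so the operator is equivariant to a simultaneous re-ordering of the
tokens of both maps.

A plain concatenation + 1x1 convolution variant is provided as the ablation
stand-in for the cross-attention operator.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .encoders import map_to_tokens, tokens_to_map
from .errors import ShapeError
from .nn import Tensor
from .nn.functional import matmul, softmax

__all__ = ["CrossAttention", "CrossAttentionFusion", "ConcatFusion"]


class CrossAttention(nn.Module):
    """Multi-head attention of one token set's queries over another's keys/values."""

    def __init__(self, dim: int, heads: int):
        super().__init__()
        if dim % heads:
            raise ShapeError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim**-0.5
        self.q = nn.Linear(dim, dim)
        self.k = nn.Linear(dim, dim)
        self.v = nn.Linear(dim, dim)
        self.last_attn: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        b, n, _ = x.shape
        return x.reshape(b, n, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, q_tokens: Tensor, kv_tokens: Tensor) -> Tensor:
        b, n, c = q_tokens.shape
        q = self._split(self.q(q_tokens))
        k = self._split(self.k(kv_tokens))
        v = self._split(self.v(kv_tokens))
        attn = softmax(matmul(q, k.swapaxes(-1, -2)) * self.scale, axis=-1)
        self.last_attn = attn.data
        out = matmul(attn, v)
        return out.transpose(0, 2, 1, 3).reshape(b, n, c)


class CrossAttentionFusion(nn.Module):
    """Bidirectional cross attention + concat + linear projection to skip width."""

    def __init__(self, dim: int, heads: int, skip_width: int | None = None, kv_pool: bool = False):
        super().__init__()
        self.dim = dim
        self.kv_pool = kv_pool
        self.attn_fg = CrossAttention(dim, heads)  # F queries, G keys/values
        self.attn_gf = CrossAttention(dim, heads)  # G queries, F keys/values
        self.proj = nn.Linear(2 * dim, skip_width or dim)
        if kv_pool:
            self.pool = nn.Conv2d(dim, dim, 2, stride=2)

    def forward(self, swin_map: Tensor, cnn_map: Tensor) -> Tensor:
        if swin_map.shape[2:] != cnn_map.shape[2:]:
            raise ShapeError(
                f"unpaired stage maps: {swin_map.shape[2:]} vs {cnn_map.shape[2:]}"
            )
        if swin_map.shape[1] != self.dim or cnn_map.shape[1] != self.dim:
            raise ShapeError("stage map channels do not match fusion width")
        grid = swin_map.shape[2:]
        f = map_to_tokens(swin_map)
        g = map_to_tokens(cnn_map)
        f_kv, g_kv = f, g
        if self.kv_pool:
            f_kv = map_to_tokens(self.pool(swin_map))
            g_kv = map_to_tokens(self.pool(cnn_map))
        a1 = self.attn_fg(f, g_kv)
        a2 = self.attn_gf(g, f_kv)
        fused = self.proj(nn.concat([a1, a2], axis=-1))
        return tokens_to_map(fused, grid)


class ConcatFusion(nn.Module):
    """Ablation stand-in for cross attention: channel concat + 1x1 convolution."""

    def __init__(self, dim: int, skip_width: int | None = None):
        super().__init__()
        self.conv = nn.Conv2d(2 * dim, skip_width or dim, 1)

    def forward(self, swin_map: Tensor, cnn_map: Tensor) -> Tensor:
        if swin_map.shape[2:] != cnn_map.shape[2:]:
            raise ShapeError(
                f"unpaired stage maps: {swin_map.shape[2:]} vs {cnn_map.shape[2:]}"
            )
        return self.conv(nn.concat([swin_map, cnn_map], axis=1))
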