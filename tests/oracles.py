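"""Independent brute-force oracles used by the test suite.

Everything here is plain NumPy, written without reference to the package's
forward implementations, so agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def linear(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None) -> np.ndarray:
    y = x @ weight.T
    return y if bias is None else y + bias


def dense_mha(
    x: np.ndarray,
    w_qkv: np.ndarray,
    b_qkv: np.ndarray,
    w_proj: np.ndarray,
    b_proj: np.ndarray,
    heads: int,
    extra_logits: np.ndarray | None = None,
) -> np.ndarray:
    """Dense multi-head self-attention on (B, N, C) tokens with fused qkv weights."""
    b, n, c = x.shape
    dh = c // heads
    qkv = linear(x, w_qkv, b_qkv)  # B,N,3C
    out = np.zeros_like(x)
    for bi in range(b):
        for h in range(heads):
            q = qkv[bi, :, h * dh : (h + 1) * dh]
            k = qkv[bi, :, c + h * dh : c + (h + 1) * dh]
            v = qkv[bi, :, 2 * c + h * dh : 2 * c + (h + 1) * dh]
            logits = q @ k.T / np.sqrt(dh)
            if extra_logits is not None:
                logits = logits + extra_logits
            a = np.exp(logits - logits.max(axis=-1, keepdims=True))
            a /= a.sum(axis=-1, keepdims=True)
            out[bi, :, h * dh : (h + 1) * dh] = a @ v
    return linear(out, w_proj, b_proj)


def dense_cross_attention(
    q_tokens: np.ndarray,
    kv_tokens: np.ndarray,
    wq, bq, wk, bk, wv, bv,
    heads: int,
) -> np.ndarray:
    """Dense multi-head cross attention with separate q/k/v projection weights."""
    b, n, c = q_tokens.shape
    dh = c // heads
    out = np.zeros_like(q_tokens)
    q_all = linear(q_tokens, wq, bq)
    k_all = linear(kv_tokens, wk, bk)
    v_all = linear(kv_tokens, wv, bv)
    for bi in range(b):
        for h in range(heads):
            sl = slice(h * dh, (h + 1) * dh)
            q, k, v = q_all[bi, :, sl], k_all[bi, :, sl], v_all[bi, :, sl]
            logits = q @ k.T / np.sqrt(dh)
            a = np.exp(logits - logits.max(axis=-1, keepdims=True))
            a /= a.sum(axis=-1, keepdims=True)
            out[bi, :, sl] = a @ v
    return out


def channel_attention(x: np.ndarray, wq, bq, wk, bk, wv, bv, wp, bp, scale: float) -> np.ndarray:
    """Explicit CxC channel attention: (softmax(Q^T K * scale) V^T)^T, then projection."""
    b, n, c = x.shape
    out = np.zeros_like(x)
    for bi in range(b):
        q = linear(x[bi], wq, bq)
        k = linear(x[bi], wk, bk)
        v = linear(x[bi], wv, bv)
        logits = q.T @ k * scale  # C x C
        a = np.exp(logits - logits.max(axis=-1, keepdims=True))
        a /= a.sum(axis=-1, keepdims=True)
        out[bi] = (a @ v.T).T
    return linear(out, wp, bp)


def shifted_window_attention(
    grid_tokens: np.ndarray,
    attn_fn,
    window: int,
    shift: int,
) -> np.ndarray:
    """Roll-and-mask oracle: roll the (H, W, C) grid by (-shift, -shift), run dense
    attention per window with a wrap mask, roll back.  ``attn_fn(tokens, mask)``
    must evaluate one window of tokens with additive mask logits."""
    h, w, c = grid_tokens.shape
    rolled = np.roll(grid_tokens, (-shift, -shift), axis=(0, 1))
    # region ids: which pre-roll block each position came from
    ids = np.zeros((h, w))
    cnt = 0
    for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
        for ws in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
            ids[hs, ws] = cnt
            cnt += 1
    out = np.zeros_like(rolled)
    for i in range(0, h, window):
        for j in range(0, w, window):
            tokens = rolled[i : i + window, j : j + window].reshape(-1, c)
            wid = ids[i : i + window, j : j + window].reshape(-1)
            mask = np.where(wid[None, :] != wid[:, None], -1e9, 0.0)
            out[i : i + window, j : j + window] = attn_fn(tokens, mask).reshape(
                window, window, c
            )
    return np.roll(out, (shift, shift), axis=(0, 1))


def bce_dice_loss(prob: np.ndarray, gt: np.ndarray) -> float:
    """Scalar-loop evaluation of 0.5*BCE + soft-Dice loss (smoothing 1)."""
    eps = 1e-7
    p = np.clip(prob, eps, 1 - eps).ravel()
    g = gt.ravel()
    bce = 0.0
    for pi, gi in zip(p, g):
        bce += -(gi * np.log(pi) + (1 - gi) * np.log(1 - pi))
    bce /= p.size
    inter = float(np.sum(prob.ravel() * g))
    dice = 1 - (2 * inter + 1) / (float(prob.sum()) + float(g.sum()) + 1)
    return 0.5 * bce + dice


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """A mask pixel is boundary if any 8-neighbour (or the frame edge) is background."""
    h, w = mask.shape
    pts = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            edge = False
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                        edge = True
            if edge:
                pts.append((y, x))
    return np.array(pts, dtype=float)


def hd_percentile(pred: np.ndarray, gt: np.ndarray, percentile: float = 95.0) -> float:
    """All-pairs pooled boundary-distance percentile (O(n^2) brute force)."""
    p_pts = boundary_pixels(pred.astype(bool))
    g_pts = boundary_pixels(gt.astype(bool))
    d = cdist(p_pts, g_pts)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pooled, percentile))


def ellipse_area_loop(size: int, center, axes) -> int:
    """Pixel-loop count of {(y,x): ((y-cy)/a)^2 + ((x-cx)/b)^2 <= 1}."""
    count = 0
    for y in range(size):
        for x in range(size):
            if ((y - center[0]) / axes[0]) ** 2 + ((x - center[1]) / axes[1]) ** 2 <= 1.0:
                count += 1
    return count


def expected_param_count_cnn_stage(in_ch: int, out_ch: int, stride: int) -> int:
    """Closed-form parameters of one residual conv stage (independent arithmetic)."""
    conv1 = in_ch * out_ch * 9 + out_ch
    conv2 = out_ch * out_ch * 9 + out_ch
    bns = 2 * (2 * out_ch)
    total = conv1 + conv2 + bns
    if in_ch != out_ch or stride != 1:
        total += in_ch * out_ch + out_ch + 2 * out_ch
    return total
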