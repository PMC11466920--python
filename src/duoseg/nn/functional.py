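"""Neural-network operators built on the autodiff :class:`~duoseg.nn.tensor.Tensor`.

Convolutions use an im2col/strided-view formulation; their adjoints (col2im)
are written out explicitly and verified against finite differences in the test
suite.  ``count_matmul_flops`` instruments every matrix product that passes
through :func:`matmul`, counting one multiplication per scalar product term —
the convention under which a (N,K) @ (K,M) product costs N*K*M.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy import special

from .tensor import Tensor

__all__ = [
    "relu",
    "gelu",
    "sigmoid",
    "softmax",
    "matmul",
    "count_matmul_flops",
    "conv2d",
    "conv_transpose2d",
]


# --------------------------------------------------------------- activations
def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    cdf = 0.5 * (1.0 + special.erf(x.data * _INV_SQRT2))

    def backward(g):
        if x.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data**2)
            x._accumulate(g * (cdf + x.data * pdf))

    return Tensor._make(x.data * cdf, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = special.expit(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# ------------------------------------------------------------- flop counting
class _MatmulCounter:
    def __init__(self):
        self.flops = 0


_COUNTERS: list[_MatmulCounter] = []


@contextmanager
def count_matmul_flops():
    """Count scalar multiplications of all matmuls executed in the block."""
    counter = _MatmulCounter()
    _COUNTERS.append(counter)
    try:
        yield counter
    finally:
        _COUNTERS.pop()


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """``a @ b`` with optional flop instrumentation (see count_matmul_flops)."""
    if _COUNTERS:
        n, k = a.shape[-2], a.shape[-1]
        m = b.shape[-1]
        batch = int(np.prod(np.broadcast_shapes(a.shape[:-2], b.shape[:-2]), initial=1))
        for c in _COUNTERS:
            c.flops += batch * n * k * m
    return a @ b


# -------------------------------------------------------------- convolutions
def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    b, c, _, _ = xp.shape
    sb, sc, sh, sw = xp.strides
    return as_strided(
        xp,
        shape=(b, c, kh, kw, ho, wo),
        strides=(sb, sc, sh, sw, sh * stride, sw * stride),
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation: x (B,Cin,H,W), w (Cout,Cin,kh,kw)."""
    bs, cin, h, ww = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin} vs weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (ww + 2 * padding - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride, ho, wo)
    out_data = np.tensordot(w.data, cols, axes=([1, 2, 3], [1, 2, 3]))  # (Cout,B,Ho,Wo)
    out_data = np.ascontiguousarray(out_data.transpose(1, 0, 2, 3))
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5])))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += np.einsum(
                        "bohw,oc->bchw", g, w.data[:, :, i, j]
                    )
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor._make(out_data, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (exact integer upsampling).

    x (B,Cin,H,W), w (Cin,Cout,k,k) with k == stride, so output windows never
    overlap and the output extent is exactly (H*k, W*k).
    """
    bs, cin, h, ww = x.shape
    cin_w, cout, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d channel mismatch: {cin} vs {cin_w}")
    if kh != stride or kw != stride:
        raise ValueError("conv_transpose2d requires kernel == stride")
    out_data = np.empty((bs, cout, h * stride, ww * stride))
    for i in range(kh):
        for j in range(kw):
            out_data[:, :, i::stride, j::stride] = np.einsum(
                "bchw,co->bohw", x.data, w.data[:, :, i, j]
            )
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    dw[:, :, i, j] = np.einsum("bchw,bohw->co", x.data, g[:, :, i::stride, j::stride])
            w._accumulate(dw)
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    dx += np.einsum("bohw,co->bchw", g[:, :, i::stride, j::stride], w.data[:, :, i, j])
            x._accumulate(dx)

    return Tensor._make(out_data, parents, backward)
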