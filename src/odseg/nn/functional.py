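"""Spatial neural-network primitives on NCHW arrays, with custom gradients.

Convolutions use an im2col strategy: ``sliding_window_view`` exposes the
receptive fields as a strided view and a single ``tensordot`` does the
contraction, so the heavy lifting stays inside BLAS. The transposed
convolution and the convolution input-gradient share one col2im
scatter loop (kh*kw slice-adds, vectorized over batch and space).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "bilinear_resize",
    "batch_norm2d",
]


def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> strided view (N,C,Ho,Wo,kh,kw)."""
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::sh, ::sw]


def _pad_hw(x: np.ndarray, p: int, value: float = 0.0) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=value)


def _scatter_windows(cols: np.ndarray, out_shape: tuple, stride: int) -> np.ndarray:
    """col2im: add (N,Cc,Ho,Wo,kh,kw) windows into a (N,Cc,Hp,Wp) buffer."""
    n, cc, ho, wo, kh, kw = cols.shape
    buf = np.zeros(out_shape, dtype=cols.dtype)
    s = stride
    for i in range(kh):
        for j in range(kw):
            buf[:, :, i : i + s * ho : s, j : j + s * wo : s] += cols[:, :, :, :, i, j]
    return buf


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. weight: (Cout, Cin, kh, kw); x: (N, Cin, H, W)."""
    x, weight = as_tensor(x), as_tensor(weight)
    if bias is not None:
        bias = as_tensor(bias)
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {cin}")
    xp = _pad_hw(x.data, padding)
    win = _windows(xp, kh, kw, stride, stride)  # (N,Cin,Ho,Wo,kh,kw)
    y = np.tensordot(win, weight.data, axes=([1, 4, 5], [1, 2, 3]))  # (N,Ho,Wo,Cout)
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
    if bias is not None:
        y = y + bias.data[None, :, None, None]
    n, _, ho, wo = y.shape

    def backward(g):
        if weight.requires_grad:
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # (Cout,Cin,kh,kw)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            cols = np.tensordot(g, weight.data, axes=([1], [0]))  # (N,Ho,Wo,Cin,kh,kw)
            cols = cols.transpose(0, 3, 1, 2, 4, 5)
            gxp = _scatter_windows(cols, xp.shape, stride)
            p = padding
            gx = gxp[:, :, p : p + x.shape[2], p : p + x.shape[3]] if p else gxp
            x._accum(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(y, parents, backward)


def conv_transpose2d(
    x, weight, bias=None, stride: int = 2, padding: int = 1, output_padding: int = 1
) -> Tensor:
    """Transposed 2-D convolution. weight: (Cin, Cout, kh, kw).

    Output spatial size: (H-1)*stride - 2*padding + kh + output_padding,
    so the 3x3/stride-2/pad-1/outpad-1 configuration exactly doubles H and W.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    if bias is not None:
        bias = as_tensor(bias)
    cin, cout, kh, kw = weight.shape
    n, cx, h, w = x.shape
    if cx != cin:
        raise ValueError(f"conv_transpose2d: input has {cx} channels, weight expects {cin}")
    s, p = stride, padding
    hout = (h - 1) * s - 2 * p + kh + output_padding
    wout = (w - 1) * s - 2 * p + kw + output_padding
    cols = np.tensordot(x.data, weight.data, axes=([1], [0]))  # (N,H,W,Cout,kh,kw)
    cols = cols.transpose(0, 3, 1, 2, 4, 5)
    buf_h, buf_w = max((h - 1) * s + kh, hout + 2 * p), max((w - 1) * s + kw, wout + 2 * p)
    buf = _scatter_windows(cols, (n, cout, buf_h, buf_w), s)
    y = np.ascontiguousarray(buf[:, :, p : p + hout, p : p + wout])
    if bias is not None:
        y = y + bias.data[None, :, None, None]

    def backward(g):
        # re-embed g where the crop took it from
        gbuf = np.zeros((n, cout, buf_h, buf_w), dtype=g.dtype)
        gbuf[:, :, p : p + hout, p : p + wout] = g
        win = _windows(gbuf[:, :, : (h - 1) * s + kh, : (w - 1) * s + kw], kh, kw, s, s)
        if x.requires_grad:
            gx = np.tensordot(win, weight.data, axes=([1, 4, 5], [1, 2, 3]))  # (N,H,W,Cin)
            x._accum(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))
        if weight.requires_grad:
            gw = np.tensordot(x.data, win, axes=([0, 2, 3], [0, 2, 3]))  # (Cin,Cout,kh,kw)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(y, parents, backward)


def max_pool2d(x, kernel_size: int, stride: int | None = None, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    k = kernel_size
    s = stride if stride is not None else k
    xp = _pad_hw(x.data, padding, value=-np.inf)
    win = _windows(xp, k, k, s, s)  # (N,C,Ho,Wo,k,k)
    n, c, ho, wo, _, _ = win.shape
    flat = win.reshape(n, c, ho, wo, k * k)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        onehot = np.zeros_like(flat)
        np.put_along_axis(onehot, idx[..., None], g[..., None], axis=-1)
        cols = onehot.reshape(n, c, ho, wo, k, k)
        gxp = _scatter_windows(cols, xp.shape, s)
        p = padding
        gx = gxp[:, :, p : p + x.shape[2], p : p + x.shape[3]] if p else gxp
        x._accum(gx)

    return Tensor._make(y, (x,), backward)


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """1-D bilinear interpolation as a dense (n_out, n_in) matrix.

    Half-pixel sample centers (align_corners=False convention), clamped
    at the borders.
    """
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for o in range(n_out):
        c = np.clip((o + 0.5) * scale - 0.5, 0.0, n_in - 1.0)
        lo = int(np.floor(c))
        hi = min(lo + 1, n_in - 1)
        t = c - lo
        m[o, lo] += 1.0 - t
        m[o, hi] += t
    return m


def bilinear_resize(x, size: tuple) -> Tensor:
    """Bilinear resize of a (N,C,H,W) tensor to spatial ``size`` (H', W')."""
    x = as_tensor(x)
    hout, wout = size
    n, c, h, w = x.shape
    r = _interp_matrix(hout, h, x.data.dtype)
    cmat = _interp_matrix(wout, w, x.data.dtype)
    y = np.tensordot(x.data, r, axes=([2], [1]))  # (N,C,W,Hout)
    y = np.tensordot(y, cmat, axes=([2], [1]))  # (N,C,Hout,Wout)

    def backward(g):
        gx = np.tensordot(g, r, axes=([2], [0]))  # (N,C,Wout,H)
        gx = np.tensordot(gx, cmat, axes=([2], [0]))  # (N,C,H,W)
        x._accum(gx)

    return Tensor._make(np.ascontiguousarray(y), (x,), backward)


def batch_norm2d(x, gamma, beta, running_mean, running_var, training: bool,
                 momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization on (N,C,H,W).

    In training mode the batch statistics are used and the running buffers
    are updated in place (biased variance in the normalizer, unbiased in
    the running estimate); in eval mode the running buffers are used.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n, c, h, w = x.shape
    if training:
        cnt = n * h * w
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        unbiased = var * cnt / max(cnt - 1, 1)
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * gamma.data[None, :, None, None]
            if training:
                cnt = n * h * w
                gsum = gi.sum(axis=(0, 2, 3), keepdims=True)
                gdot = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gi - gsum / cnt - xhat * gdot / cnt) * inv[None, :, None, None]
            else:
                gx = gi * inv[None, :, None, None]
            x._accum(gx)

    return Tensor._make(y, (x, gamma, beta), backward)
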