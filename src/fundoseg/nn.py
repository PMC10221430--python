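"""Minimal CPU neural-network primitives for the U-Net.

Arrays are NCHW float32.  Each functional op returns its output plus a
cache; the matching ``*_backward`` consumes the upstream gradient and the
cache.  Everything is plain numpy, so results are bit-reproducible on one
CPU for a fixed seed.

Shapes are restricted to what the U-Net needs: 3x3 same-padding
convolutions, 1x1 convolutions, 2x2 max pooling, and 2x2/stride-2
transposed convolutions (which exactly tile the output, so no overlap
handling is needed).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d",
    "conv2d_backward",
    "conv_transpose2x2",
    "conv_transpose2x2_backward",
    "maxpool2x2",
    "maxpool2x2_backward",
    "relu",
    "relu_backward",
    "sigmoid",
    "Adam",
]


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padding stride-1 convolution (cross-correlation).

    x: (N, C, H, W); w: (O, C, k, k) with odd k; b: (O,).
    """
    k = w.shape[-1]
    pad = (k - 1) // 2
    if pad:
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = x
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    out = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # N,H,W,O
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    out += b[None, :, None, None]
    return out, (xp, w, x.shape)


def conv2d_backward(dout: np.ndarray, cache):
    xp, w, x_shape = cache
    k = w.shape[-1]
    pad = (k - 1) // 2
    N, C, H, W = x_shape

    db = dout.sum(axis=(0, 2, 3))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    # dw[o,c,i,j] = sum_{n,h,w} dout[n,o,h,w] * xp[n,c,h+i,w+j]
    dw = np.tensordot(dout, win, axes=([0, 2, 3], [0, 2, 3]))  # O,C,k,k

    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            # dout (N,O,H,W) x w[:,:,i,j] (O,C) -> (N,C,H,W)
            contrib = np.tensordot(dout, w[:, :, i, j], axes=([1], [0]))  # N,H,W,C
            dxp[:, :, i : i + H, j : j + W] += contrib.transpose(0, 3, 1, 2)
    dx = dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp
    return np.ascontiguousarray(dx), dw.astype(w.dtype), db.astype(w.dtype)


def conv_transpose2x2(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling).

    x: (N, C, H, W); w: (C, O, 2, 2); b: (O,).  Output (N, O, 2H, 2W);
    output patch (2h+i, 2w+j) receives sum_c x[...,h,w] * w[c,o,i,j].
    """
    N, C, H, W = x.shape
    O = w.shape[1]
    y = np.einsum("nchw,coij->nohiwj", x, w, optimize=True)
    y = y.reshape(N, O, 2 * H, 2 * W)
    y = np.ascontiguousarray(y)
    y += b[None, :, None, None]
    return y, (x, w)


def conv_transpose2x2_backward(dout: np.ndarray, cache):
    x, w = cache
    N, C, H, W = x.shape
    O = w.shape[1]
    dyr = dout.reshape(N, O, H, 2, W, 2)
    db = dout.sum(axis=(0, 2, 3)).astype(w.dtype)
    dw = np.einsum("nchw,nohiwj->coij", x, dyr, optimize=True).astype(w.dtype)
    dx = np.einsum("nohiwj,coij->nchw", dyr, w, optimize=True).astype(x.dtype)
    return np.ascontiguousarray(dx), dw, db


def maxpool2x2(x: np.ndarray):
    N, C, H, W = x.shape
    xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = np.ascontiguousarray(xr).reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(out), (idx, x.shape)


def maxpool2x2_backward(dout: np.ndarray, cache):
    idx, x_shape = cache
    N, C, H, W = x_shape
    dflat = np.zeros((N, C, H // 2, W // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
    dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(x_shape)


def relu(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, (x > 0)


def relu_backward(dout: np.ndarray, cache):
    return dout * cache


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
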