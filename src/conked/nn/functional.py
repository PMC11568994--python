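"""Low-level array operations for small convolutional networks.

All operations work on float32 arrays shaped ``(B, C, H, W)`` (batch,
channels, rows, cols) with stride 1; spatial subsampling is done by explicit
pooling layers.  Convolution accumulates one GEMM per kernel tap
(y += w[:, :, i, j] @ x shifted by (i, j)), which keeps every matrix
contiguous and avoids im2col gather copies; the input gradient is expressed
as a convolution of the output gradient with the flipped kernel, so the one
forward primitive serves both passes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_backward",
    "maxpool2",
    "maxpool2_backward",
    "upsample2",
    "upsample2_backward",
]


def _pad(x, pad):
    if pad:
        return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return x


def conv2d(x, w, b=None, pad=0, dilation=1):
    """2-D cross-correlation, stride 1.

    x: (B, C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    Returns (B, O, Ho, Wo) with Ho = H + 2*pad - ((kh-1)*dilation + 1) + 1.
    """
    o, c, kh, kw = w.shape
    bsz = x.shape[0]
    xp = _pad(x, pad)
    ho = xp.shape[2] - (kh - 1) * dilation
    wo = xp.shape[3] - (kw - 1) * dilation
    p = ho * wo
    y = np.zeros((bsz, o, p), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            di, dj = i * dilation, j * dilation
            xv = xp[:, :, di : di + ho, dj : dj + wo]
            xv = np.ascontiguousarray(xv).reshape(bsz, c, p)
            # (B, O, P) += (O, C) @ (B, C, P)
            y += w[:, :, i, j] @ xv
    if b is not None:
        y += b[:, None]
    return y.reshape(bsz, o, ho, wo)


def conv2d_backward(gy, x, w, pad=0, dilation=1):
    """Gradients of conv2d.  Returns (gx, gw, gb)."""
    o, c, kh, kw = w.shape
    bsz = gy.shape[0]
    ho, wo = gy.shape[2], gy.shape[3]
    p = ho * wo
    gyf = gy.reshape(bsz, o, p)
    xp = _pad(x, pad)
    gw = np.empty_like(w)
    for i in range(kh):
        for j in range(kw):
            di, dj = i * dilation, j * dilation
            xv = xp[:, :, di : di + ho, dj : dj + wo]
            xv = np.ascontiguousarray(xv).reshape(bsz, c, p)
            # (O, C) = sum_b (O, P) @ (P, C)
            gw[:, :, i, j] = np.einsum(
                "bop,bcp->oc", gyf, xv, optimize=True
            )
    gb = gy.sum(axis=(0, 2, 3))
    # input gradient: full correlation with channel-swapped, flipped kernel
    ke = (kh - 1) * dilation + 1
    w_flip = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    gx = conv2d(gy, w_flip, pad=ke - 1 - pad, dilation=dilation)
    return gx, gw, gb


def maxpool2(x):
    """2x2 max pooling, stride 2.  H and W must be even."""
    b, c, h, w = x.shape
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    return y, xr


def maxpool2_backward(gy, xr, y):
    mask = xr == y[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True)
    gx = mask * (gy[:, :, :, None, :, None] / counts)
    b, c, h2, _, w2, _ = xr.shape
    return gx.reshape(b, c, h2 * 2, w2 * 2)


def upsample2(x):
    """Nearest-neighbour 2x upsampling."""
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(gy):
    b, c, h, w = gy.shape
    return gy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
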