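"""Direct convolution kernels.

The convolutions dominate the runtime of every forward/backward pass; a
naive im2col implementation spends most of its time copying strided
patch matrices, so the forward pass and both backward contractions are
written as direct loops compiled with numba (fastmath: summation order may
be reassociated, differences are at rounding level).  A pure-numpy im2col
fallback keeps the package importable if numba is unavailable.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["conv2d_forward", "conv2d_backward_dx", "conv2d_backward_dw", "HAVE_NUMBA"]

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False, fastmath=True)
def _fwd(xp, w):
    B, C, Hp, Wp = xp.shape
    O, _, kh, kw = w.shape
    H, W = Hp - kh + 1, Wp - kw + 1
    y = np.zeros((B, O, H, W))
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        wv = w[o, c, i, j]
                        for h in range(H):
                            for x in range(W):
                                y[b, o, h, x] += wv * xp[b, c, h + i, x + j]
    return y


@njit(cache=False, fastmath=True)
def _bwd_dx(gy, w):
    B, O, H, W = gy.shape
    _, C, kh, kw = w.shape
    gxp = np.zeros((B, C, H + kh - 1, W + kw - 1))
    for b in range(B):
        for c in range(C):
            for o in range(O):
                for i in range(kh):
                    for j in range(kw):
                        wv = w[o, c, i, j]
                        for h in range(H):
                            for x in range(W):
                                gxp[b, c, h + i, x + j] += wv * gy[b, o, h, x]
    return gxp


@njit(cache=False, fastmath=True)
def _bwd_dw(gy, xp, kh, kw):
    B, O, H, W = gy.shape
    C = xp.shape[1]
    gw = np.zeros((O, C, kh, kw))
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        s = 0.0
                        for h in range(H):
                            for x in range(W):
                                s += xp[b, c, h + i, x + j] * gy[b, o, h, x]
                        gw[o, c, i, j] += s
    return gw


def _pad(x, kh, kw):
    ph, pw = kh // 2, kw // 2
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


if HAVE_NUMBA:

    def conv2d_forward(x, w):
        """Same-padding stride-1 conv: x (B,C,H,W), w (O,C,kh,kw) -> (B,O,H,W)."""
        return _fwd(_pad(x, w.shape[2], w.shape[3]), w)

    def conv2d_backward_dx(gy, w):
        """Gradient w.r.t. x: full correlation of gy with the flipped kernel."""
        kh, kw = w.shape[2], w.shape[3]
        ph, pw = kh // 2, kw // 2
        gxp = _bwd_dx(gy, w)
        H = gxp.shape[2] - 2 * ph
        W = gxp.shape[3] - 2 * pw
        return gxp[:, :, ph : ph + H, pw : pw + W]

    def conv2d_backward_dw(gy, x, kh, kw):
        return _bwd_dw(gy, _pad(x, kh, kw), kh, kw)

else:  # pragma: no cover - exercised only without numba

    def _im2col(x, kh, kw):
        B, C, H, W = x.shape
        win = sliding_window_view(_pad(x, kh, kw), (kh, kw), axis=(2, 3))
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * kh * kw)

    def conv2d_forward(x, w):
        B, C, H, W = x.shape
        O, _, kh, kw = w.shape
        y = _im2col(x, kh, kw) @ w.reshape(O, -1).T
        return y.transpose(0, 2, 1).reshape(B, O, H, W)

    def conv2d_backward_dx(gy, w):
        O, C, kh, kw = w.shape
        flipped = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return conv2d_forward(gy, np.ascontiguousarray(flipped))

    def conv2d_backward_dw(gy, x, kh, kw):
        B, O, H, W = gy.shape
        col = _im2col(x, kh, kw)
        g2 = gy.reshape(B, O, H * W).transpose(0, 2, 1)
        return np.einsum("bpo,bpk->ok", g2, col).reshape(O, -1, kh, kw)
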