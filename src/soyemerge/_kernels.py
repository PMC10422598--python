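"""Numba-accelerated convolution kernels.

Stride-1 same-padding convolution forward/backward as fused scalar loops,
laid out channel-first internally so the innermost loops run over contiguous
image rows and auto-vectorise. Used by the network layers when numba is
importable; the layers fall back to a pure-NumPy path otherwise, with
identical results.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAS_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    HAS_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def conv_fwd(xp, W, b, out):  # pragma: no cover - exercised via _Conv2D
    """xp (n, cin, hp, wp), W (k, k, cin, cout), b (cout) -> out (n, cout, h, w)."""
    n, cout, h, w = out.shape
    k = W.shape[0]
    cin = W.shape[2]
    tmp = np.empty(w, dtype=np.float32)
    for im in range(n):
        for o in range(cout):
            for i in range(h):
                for j in range(w):
                    tmp[j] = b[o]
                for ki in range(k):
                    for c in range(cin):
                        xrow = xp[im, c, i + ki]
                        for kj in range(k):
                            wv = W[ki, kj, c, o]
                            for j in range(w):
                                tmp[j] += xrow[j + kj] * wv
                for j in range(w):
                    out[im, o, i, j] = tmp[j]


@njit(cache=True, fastmath=True)
def conv_bwd(xp, W, dy, dxp, dW, db):  # pragma: no cover - exercised via _Conv2D
    """Gradients of conv_fwd; dy (n, cout, h, w), dxp/dW/db accumulated in place."""
    n, cout, h, w = dy.shape
    k = W.shape[0]
    cin = W.shape[2]
    for im in range(n):
        for o in range(cout):
            for i in range(h):
                dyrow = dy[im, o, i]
                s = np.float32(0.0)
                for j in range(w):
                    s += dyrow[j]
                db[o] += s
                for ki in range(k):
                    for c in range(cin):
                        xrow = xp[im, c, i + ki]
                        dxrow = dxp[im, c, i + ki]
                        for kj in range(k):
                            wv = W[ki, kj, c, o]
                            acc = np.float32(0.0)
                            for j in range(w):
                                dxrow[j + kj] += dyrow[j] * wv
                                acc += xrow[j + kj] * dyrow[j]
                            dW[ki, kj, c, o] += acc


@njit(cache=True, fastmath=True)
def lrn_denom(x, win, alpha, kconst, d):  # pragma: no cover
    """Channel-last LRN denominator: d = k + (alpha/win) * sliding channel sum of x^2.

    The (-beta) power is applied outside with vectorised NumPy, which is
    faster than a scalar pow in the loop.
    """
    n, h, w, c = x.shape
    r = win // 2
    coef = alpha / win
    for im in range(n):
        for i in range(h):
            for j in range(w):
                for ci in range(c):
                    lo = max(ci - r, 0)
                    hi = min(ci + r + 1, c)
                    s = np.float32(0.0)
                    for cj in range(lo, hi):
                        v = x[im, i, j, cj]
                        s += v * v
                    d[im, i, j, ci] = kconst + coef * s


@njit(cache=True, fastmath=True)
def lrn_bwd(x, d, dpow, dy, win, alpha, beta, dx):  # pragma: no cover
    n, h, w, c = x.shape
    r = win // 2
    coef = 2.0 * alpha * beta / win
    t = np.empty(c, dtype=np.float32)
    for im in range(n):
        for i in range(h):
            for j in range(w):
                for ci in range(c):
                    t[ci] = dy[im, i, j, ci] * x[im, i, j, ci] \
                        * dpow[im, i, j, ci] / d[im, i, j, ci]
                for ci in range(c):
                    lo = max(ci - r, 0)
                    hi = min(ci + r + 1, c)
                    s = np.float32(0.0)
                    for cj in range(lo, hi):
                        s += t[cj]
                    dx[im, i, j, ci] = dy[im, i, j, ci] * dpow[im, i, j, ci] \
                        - coef * x[im, i, j, ci] * s


@njit(cache=True, fastmath=True)
def pool_fwd(x, win, stride, y, idx):  # pragma: no cover
    """Channel-last overlapping max pool; idx stores the winning window offset."""
    n, ho, wo, c = y.shape
    for im in range(n):
        for i in range(ho):
            for j in range(wo):
                for ci in range(c):
                    best = np.float32(-1e30)
                    bp = 0
                    for ki in range(win):
                        for kj in range(win):
                            v = x[im, i * stride + ki, j * stride + kj, ci]
                            if v > best:
                                best = v
                                bp = ki * win + kj
                    y[im, i, j, ci] = best
                    idx[im, i, j, ci] = bp


@njit(cache=True, fastmath=True)
def pool_bwd(dy, idx, win, stride, dx):  # pragma: no cover
    n, ho, wo, c = dy.shape
    dx[:] = 0.0
    for im in range(n):
        for i in range(ho):
            for j in range(wo):
                for ci in range(c):
                    p = idx[im, i, j, ci]
                    ki = p // win
                    kj = p % win
                    dx[im, i * stride + ki, j * stride + kj, ci] += dy[im, i, j, ci]
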