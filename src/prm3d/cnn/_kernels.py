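"""Numba kernels for the memory-bound pieces of the conv/pool layers.

These replace numpy strided copies whose inner contiguous runs are too
short for the ufunc machinery to stream efficiently (column-buffer fills,
gradient scatter, 2×2×2 pooling).  All kernels are single-threaded and
bit-deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def im2col9(xp, cols):
    """cols[n, p, j, k, (3b+cc)c+ch] = xp[n, p, j+b, k+cc, ch]."""
    n, dp, hp, wp, c = xp.shape
    h, w = hp - 2, wp - 2
    for i in range(n):
        for p in range(dp):
            for b in range(3):
                for cc in range(3):
                    o = (b * 3 + cc) * c
                    for j in range(h):
                        for k in range(w):
                            for ch in range(c):
                                cols[i, p, j, k, o + ch] = xp[i, p, j + b, k + cc, ch]


@njit(cache=True)
def im2col27(xp, cols):
    """Full 27-offset buffer for narrow-channel convolutions."""
    n, dp, hp, wp, c = xp.shape
    d, h, w = dp - 2, hp - 2, wp - 2
    for i in range(n):
        for p in range(d):
            for a in range(3):
                for b in range(3):
                    for cc in range(3):
                        o = ((a * 3 + b) * 3 + cc) * c
                        for j in range(h):
                            for k in range(w):
                                for ch in range(c):
                                    cols[i, p, j, k, o + ch] = xp[
                                        i, p + a, j + b, k + cc, ch
                                    ]


@njit(cache=True)
def colscatter9(dcols, dxp):
    """dxp[n, p, j+b, k+cc, ch] += dcols[n, p, j, k, (3b+cc)c+ch]."""
    n, dp, hp, wp, c = dxp.shape
    h, w = hp - 2, wp - 2
    for i in range(n):
        for p in range(dp):
            for b in range(3):
                for cc in range(3):
                    o = (b * 3 + cc) * c
                    for j in range(h):
                        for k in range(w):
                            for ch in range(c):
                                dxp[i, p, j + b, k + cc, ch] += dcols[
                                    i, p, j, k, o + ch
                                ]


@njit(cache=True)
def conv_out3(y, b, out):
    """out[n,i,...,f] = Σ_a y[n,i+a,...,a,f] + b[f] (depth-shift assembly)."""
    n, dp, h, w, _, f = y.shape
    d = dp - 2
    for i in range(n):
        for p in range(d):
            for j in range(h):
                for k in range(w):
                    for ch in range(f):
                        out[i, p, j, k, ch] = (
                            y[i, p, j, k, 0, ch]
                            + y[i, p + 1, j, k, 1, ch]
                            + y[i, p + 2, j, k, 2, ch]
                            + b[ch]
                        )


@njit(cache=True)
def bn_transform(x, gamma, beta, mean, inv, xhat, out):
    """xhat = (x−mean)·inv and out = γ·xhat + β in one pass (channels last)."""
    m, c = x.shape
    for i in range(m):
        for ch in range(c):
            v = (x[i, ch] - mean[ch]) * inv[ch]
            xhat[i, ch] = v
            out[i, ch] = gamma[ch] * v + beta[ch]


@njit(cache=True)
def bn_backward_dx(dy, xhat, gamma, inv, dgamma, dbeta, m):
    """dx = γ·inv·(dy − Σdy/m − x̂·Σ(dy·x̂)/m), written into dy in place."""
    rows, c = dy.shape
    gi = np.empty(c, dtype=np.float32)
    db = np.empty(c, dtype=np.float32)
    dg = np.empty(c, dtype=np.float32)
    for ch in range(c):
        gi[ch] = gamma[ch] * inv[ch]
        db[ch] = dbeta[ch] / m
        dg[ch] = dgamma[ch] / m
    for i in range(rows):
        for ch in range(c):
            dy[i, ch] = gi[ch] * (dy[i, ch] - db[ch] - xhat[i, ch] * dg[ch])


@njit(cache=True)
def relu_fwd(x1, mask1):
    """In-place ReLU on a flat contiguous view, recording the pass mask."""
    for i in range(x1.size):
        if x1[i] > 0:
            mask1[i] = True
        else:
            mask1[i] = False
            x1[i] = 0.0


@njit(cache=True)
def maxpool_fwd(x, out, arg):
    """2×2×2 max with argmax codes 0..7 ((dz<<2)|(dy<<1)|dx)."""
    n, d, h, w, c = x.shape
    for i in range(n):
        for dd in range(d // 2):
            for hh in range(h // 2):
                for ww in range(w // 2):
                    for z in range(8):
                        a0 = 2 * dd + (z >> 2)
                        b0 = 2 * hh + ((z >> 1) & 1)
                        c0 = 2 * ww + (z & 1)
                        if z == 0:
                            for ch in range(c):
                                out[i, dd, hh, ww, ch] = x[i, a0, b0, c0, ch]
                                arg[i, dd, hh, ww, ch] = 0
                        else:
                            for ch in range(c):
                                v = x[i, a0, b0, c0, ch]
                                if v > out[i, dd, hh, ww, ch]:
                                    out[i, dd, hh, ww, ch] = v
                                    arg[i, dd, hh, ww, ch] = z
    return out


@njit(cache=True)
def maxpool_bwd(dy, arg, dx):
    n, d2, h2, w2, c = dy.shape
    for i in range(n):
        for dd in range(d2):
            for hh in range(h2):
                for ww in range(w2):
                    for ch in range(c):
                        z = arg[i, dd, hh, ww, ch]
                        dx[i, 2 * dd + (z >> 2), 2 * hh + ((z >> 1) & 1),
                           2 * ww + (z & 1), ch] = dy[i, dd, hh, ww, ch]
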