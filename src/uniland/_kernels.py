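"""Numba-compiled inner loops for the bandwidth-bound layers.

The GEMM-shaped work (point-wise and im2col convolutions) stays on BLAS;
these kernels cover the operations NumPy cannot fuse: depthwise 3x3
convolution, leaky ReLU, and 2x2 max pooling.  All loops are sequential and
in a fixed order, so results are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def dw3x3_forward(xp, w):
    """xp: (B, C, H+2, W+2) padded input; w: (C, 3, 3) -> (B, C, H, W)."""
    b, c, hp, wp = xp.shape
    h, wi = hp - 2, wp - 2
    y = np.empty((b, c, h, wi), dtype=xp.dtype)
    for bb in range(b):
        for cc in range(c):
            w00 = w[cc, 0, 0]; w01 = w[cc, 0, 1]; w02 = w[cc, 0, 2]
            w10 = w[cc, 1, 0]; w11 = w[cc, 1, 1]; w12 = w[cc, 1, 2]
            w20 = w[cc, 2, 0]; w21 = w[cc, 2, 1]; w22 = w[cc, 2, 2]
            for i in range(h):
                for j in range(wi):
                    y[bb, cc, i, j] = (
                        w00 * xp[bb, cc, i, j]
                        + w01 * xp[bb, cc, i, j + 1]
                        + w02 * xp[bb, cc, i, j + 2]
                        + w10 * xp[bb, cc, i + 1, j]
                        + w11 * xp[bb, cc, i + 1, j + 1]
                        + w12 * xp[bb, cc, i + 1, j + 2]
                        + w20 * xp[bb, cc, i + 2, j]
                        + w21 * xp[bb, cc, i + 2, j + 1]
                        + w22 * xp[bb, cc, i + 2, j + 2]
                    )
    return y


@njit(cache=True)
def dw3x3_backward(xp, w, gy):
    """Returns (gx, gw) for the depthwise 3x3 forward above.

    The input gradient is the correlation of gy with the 180-degree-rotated
    kernel (sequential reads instead of scattered writes); the weight
    gradient accumulates into per-channel registers.
    """
    b, c, hp, wp = xp.shape
    h, wi = hp - 2, wp - 2
    gx = np.empty((b, c, h, wi), dtype=xp.dtype)
    gw = np.zeros(w.shape, dtype=w.dtype)
    for bb in range(b):
        for cc in range(c):
            # weight gradient: gw[di, dj] = sum_ij gy[i, j] * xp[i+di, j+dj]
            a00 = a01 = a02 = a10 = a11 = a12 = a20 = a21 = a22 = 0.0
            for i in range(h):
                for j in range(wi):
                    g = gy[bb, cc, i, j]
                    a00 += g * xp[bb, cc, i, j]
                    a01 += g * xp[bb, cc, i, j + 1]
                    a02 += g * xp[bb, cc, i, j + 2]
                    a10 += g * xp[bb, cc, i + 1, j]
                    a11 += g * xp[bb, cc, i + 1, j + 1]
                    a12 += g * xp[bb, cc, i + 1, j + 2]
                    a20 += g * xp[bb, cc, i + 2, j]
                    a21 += g * xp[bb, cc, i + 2, j + 1]
                    a22 += g * xp[bb, cc, i + 2, j + 2]
            gw[cc, 0, 0] += a00; gw[cc, 0, 1] += a01; gw[cc, 0, 2] += a02
            gw[cc, 1, 0] += a10; gw[cc, 1, 1] += a11; gw[cc, 1, 2] += a12
            gw[cc, 2, 0] += a20; gw[cc, 2, 1] += a21; gw[cc, 2, 2] += a22
            # input gradient: correlation of gy with the flipped kernel
            w00 = w[cc, 2, 2]; w01 = w[cc, 2, 1]; w02 = w[cc, 2, 0]
            w10 = w[cc, 1, 2]; w11 = w[cc, 1, 1]; w12 = w[cc, 1, 0]
            w20 = w[cc, 0, 2]; w21 = w[cc, 0, 1]; w22 = w[cc, 0, 0]
            for i in range(h):
                for j in range(wi):
                    acc = 0.0
                    if i > 0:
                        if j > 0:
                            acc += w00 * gy[bb, cc, i - 1, j - 1]
                        acc += w01 * gy[bb, cc, i - 1, j]
                        if j < wi - 1:
                            acc += w02 * gy[bb, cc, i - 1, j + 1]
                    if j > 0:
                        acc += w10 * gy[bb, cc, i, j - 1]
                    acc += w11 * gy[bb, cc, i, j]
                    if j < wi - 1:
                        acc += w12 * gy[bb, cc, i, j + 1]
                    if i < h - 1:
                        if j > 0:
                            acc += w20 * gy[bb, cc, i + 1, j - 1]
                        acc += w21 * gy[bb, cc, i + 1, j]
                        if j < wi - 1:
                            acc += w22 * gy[bb, cc, i + 1, j + 1]
                    gx[bb, cc, i, j] = acc
    return gx, gw


@njit(cache=True)
def bn_forward_train(x, gamma, beta, eps):
    """Fused train-mode batch norm: returns (y, xhat, mean, var, invstd)."""
    b, c, h, w = x.shape
    n = b * h * w
    mean = np.empty(c, dtype=x.dtype)
    var = np.empty(c, dtype=x.dtype)
    invstd = np.empty(c, dtype=x.dtype)
    y = np.empty_like(x)
    xhat = np.empty_like(x)
    for cc in range(c):
        s = 0.0
        s2 = 0.0
        for bb in range(b):
            for i in range(h):
                for j in range(w):
                    v = x[bb, cc, i, j]
                    s += v
                    s2 += v * v
        m = s / n
        v2 = s2 / n - m * m
        if v2 < 0.0:
            v2 = 0.0
        mean[cc] = m
        var[cc] = v2
        istd = 1.0 / np.sqrt(v2 + eps)
        invstd[cc] = istd
        g = gamma[cc]
        be = beta[cc]
        for bb in range(b):
            for i in range(h):
                for j in range(w):
                    xh = (x[bb, cc, i, j] - m) * istd
                    xhat[bb, cc, i, j] = xh
                    y[bb, cc, i, j] = g * xh + be
    return y, xhat, mean, var, invstd


@njit(cache=True)
def bn_backward_train(xhat, invstd, gamma, gy):
    """Returns (gx, ggamma, gbeta) for fused train-mode batch norm."""
    b, c, h, w = xhat.shape
    n = b * h * w
    gx = np.empty_like(gy)
    ggamma = np.empty(c, dtype=gamma.dtype)
    gbeta = np.empty(c, dtype=gamma.dtype)
    for cc in range(c):
        s1 = 0.0
        s2 = 0.0
        for bb in range(b):
            for i in range(h):
                for j in range(w):
                    g = gy[bb, cc, i, j]
                    s1 += g
                    s2 += g * xhat[bb, cc, i, j]
        ggamma[cc] = s2
        gbeta[cc] = s1
        k = gamma[cc] * invstd[cc]
        m1 = s1 / n
        m2 = s2 / n
        for bb in range(b):
            for i in range(h):
                for j in range(w):
                    gx[bb, cc, i, j] = k * (
                        gy[bb, cc, i, j] - m1 - xhat[bb, cc, i, j] * m2
                    )
    return gx, ggamma, gbeta


@njit(cache=True)
def leaky_forward(x, slope):
    y = np.empty_like(x)
    xf = x.ravel()
    yf = y.ravel()
    for k in range(xf.size):
        v = xf[k]
        yf[k] = v if v > 0 else slope * v
    return y


@njit(cache=True)
def leaky_backward(y, gy, slope):
    gx = np.empty_like(gy)
    yf = y.ravel()
    gf = gy.ravel()
    of = gx.ravel()
    for k in range(yf.size):
        of[k] = gf[k] if yf[k] > 0 else slope * gf[k]
    return gx


@njit(cache=True)
def maxpool2x2_forward(x):
    b, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    y = np.empty((b, c, h2, w2), dtype=x.dtype)
    idx = np.empty((b, c, h2, w2), dtype=np.uint8)
    for bb in range(b):
        for cc in range(c):
            for i in range(h2):
                for j in range(w2):
                    v00 = x[bb, cc, 2 * i, 2 * j]
                    v01 = x[bb, cc, 2 * i, 2 * j + 1]
                    v10 = x[bb, cc, 2 * i + 1, 2 * j]
                    v11 = x[bb, cc, 2 * i + 1, 2 * j + 1]
                    best, k = v00, np.uint8(0)
                    if v01 > best:
                        best, k = v01, np.uint8(1)
                    if v10 > best:
                        best, k = v10, np.uint8(2)
                    if v11 > best:
                        best, k = v11, np.uint8(3)
                    y[bb, cc, i, j] = best
                    idx[bb, cc, i, j] = k
    return y, idx


@njit(cache=True)
def maxpool2x2_backward(idx, gy):
    b, c, h2, w2 = gy.shape
    gx = np.zeros((b, c, 2 * h2, 2 * w2), dtype=gy.dtype)
    for bb in range(b):
        for cc in range(c):
            for i in range(h2):
                for j in range(w2):
                    k = idx[bb, cc, i, j]
                    gx[bb, cc, 2 * i + (k >> 1), 2 * j + (k & 1)] = gy[bb, cc, i, j]
    return gx
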