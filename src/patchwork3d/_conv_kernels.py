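"""Numba-jitted direct 3x3x3 convolution kernels.

Single-core cache-friendly loops: each 32-voxel output row stays in
registers/L1 while all kernel taps accumulate into it, so the kernels are
arithmetic-bound rather than copy-bound (unlike an im2col lowering).
Numerics are identical to the GEMM reference path in ``_nn`` up to float32
summation order; the test suite checks agreement.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = [
    "conv3d_k3",
    "conv3d_k3_gw",
    "conv3d_k1",
    "conv3d_k1_gw",
    "instnorm_fwd",
    "instnorm_bwd",
    "maxpool2_fwd",
    "maxpool2_bwd",
]


@numba.njit(cache=True, fastmath=True)
def conv3d_k3(xp: np.ndarray, W: np.ndarray, out: np.ndarray) -> None:
    """Same-padding k=3 convolution. xp is the pre-padded input.

    xp: (B, Ci, D+2, H+2, W+2); W: (Co, Ci, 3, 3, 3); out: (B, Co, D, H, W),
    pre-filled with the bias (or zeros).
    """
    B, Co, D, H, Wd = out.shape
    Ci = xp.shape[1]
    for b in range(B):
        for co in range(Co):
            for x in range(D):
                for y in range(H):
                    row = out[b, co, x, y]
                    for ci in range(Ci):
                        for dz in range(3):
                            for dy in range(3):
                                xrow = xp[b, ci, x + dz, y + dy]
                                w0 = W[co, ci, dz, dy, 0]
                                w1 = W[co, ci, dz, dy, 1]
                                w2 = W[co, ci, dz, dy, 2]
                                for z in range(Wd):
                                    row[z] += (
                                        w0 * xrow[z] + w1 * xrow[z + 1] + w2 * xrow[z + 2]
                                    )


@numba.njit(cache=True, fastmath=True)
def conv3d_k3_gw(xp: np.ndarray, gy: np.ndarray, gW: np.ndarray) -> None:
    """Kernel gradient of the k=3 convolution.

    xp: padded input (B, Ci, D+2, H+2, W+2); gy: (B, Co, D, H, W);
    gW: (Co, Ci, 3, 3, 3) accumulated in place.
    """
    B, Co, D, H, Wd = gy.shape
    Ci = xp.shape[1]
    for b in range(B):
        for co in range(Co):
            for ci in range(Ci):
                for dz in range(3):
                    for dy in range(3):
                        a0 = 0.0
                        a1 = 0.0
                        a2 = 0.0
                        for x in range(D):
                            for y in range(H):
                                grow = gy[b, co, x, y]
                                xrow = xp[b, ci, x + dz, y + dy]
                                for z in range(Wd):
                                    g = grow[z]
                                    a0 += g * xrow[z]
                                    a1 += g * xrow[z + 1]
                                    a2 += g * xrow[z + 2]
                        gW[co, ci, dz, dy, 0] += a0
                        gW[co, ci, dz, dy, 1] += a1
                        gW[co, ci, dz, dy, 2] += a2


@numba.njit(cache=True, fastmath=True)
def conv3d_k1(x: np.ndarray, W: np.ndarray, out: np.ndarray) -> None:
    """Pointwise (1x1x1) convolution; out pre-filled with the bias."""
    B, Co, D, H, Wd = out.shape
    Ci = x.shape[1]
    for b in range(B):
        for co in range(Co):
            for ci in range(Ci):
                w = W[co, ci]
                for xx in range(D):
                    for y in range(H):
                        row = out[b, co, xx, y]
                        xrow = x[b, ci, xx, y]
                        for z in range(Wd):
                            row[z] += w * xrow[z]


@numba.njit(cache=True, fastmath=True)
def conv3d_k1_gw(x: np.ndarray, gy: np.ndarray, gW: np.ndarray) -> None:
    """Kernel gradient of the pointwise convolution (accumulated in place)."""
    B, Co, D, H, Wd = gy.shape
    Ci = x.shape[1]
    for b in range(B):
        for co in range(Co):
            for ci in range(Ci):
                acc = 0.0
                for xx in range(D):
                    for y in range(H):
                        grow = gy[b, co, xx, y]
                        xrow = x[b, ci, xx, y]
                        for z in range(Wd):
                            acc += grow[z] * xrow[z]
                gW[co, ci] += acc


@numba.njit(cache=True, fastmath=True)
def instnorm_fwd(x, gamma, beta, eps, y, xhat, istd):
    """Instance norm forward; fills y, xhat and per-(sample,channel) istd."""
    B, C = x.shape[0], x.shape[1]
    n = x.shape[2] * x.shape[3] * x.shape[4]
    xf = x.reshape(B, C, n)
    yf = y.reshape(B, C, n)
    hf = xhat.reshape(B, C, n)
    for b in range(B):
        for c in range(C):
            s = 0.0
            s2 = 0.0
            row = xf[b, c]
            for i in range(n):
                v = row[i]
                s += v
                s2 += v * v
            mean = s / n
            var = s2 / n - mean * mean
            if var < 0.0:
                var = 0.0
            inv = 1.0 / np.sqrt(var + eps)
            istd[b, c] = inv
            g = gamma[c]
            bb = beta[c]
            hrow = hf[b, c]
            yrow = yf[b, c]
            for i in range(n):
                h = (row[i] - mean) * inv
                hrow[i] = h
                yrow[i] = g * h + bb


@numba.njit(cache=True, fastmath=True)
def instnorm_bwd(gy, xhat, istd, gamma, gx, ggamma, gbeta):
    """Instance norm backward; accumulates ggamma/gbeta, fills gx."""
    B, C = gy.shape[0], gy.shape[1]
    n = gy.shape[2] * gy.shape[3] * gy.shape[4]
    gf = gy.reshape(B, C, n)
    hf = xhat.reshape(B, C, n)
    xf = gx.reshape(B, C, n)
    for b in range(B):
        for c in range(C):
            grow = gf[b, c]
            hrow = hf[b, c]
            sg = 0.0
            sgh = 0.0
            for i in range(n):
                g = grow[i]
                sg += g
                sgh += g * hrow[i]
            ggamma[c] += sgh
            gbeta[c] += sg
            gam = gamma[c]
            m1 = gam * sg / n
            m2 = gam * sgh / n
            inv = istd[b, c]
            orow = xf[b, c]
            for i in range(n):
                orow[i] = inv * (gam * grow[i] - m1 - hrow[i] * m2)


@numba.njit(cache=True, fastmath=True)
def maxpool2_fwd(x, out, idx):
    """2x2x2 max pooling; idx records the argmax corner (0..7)."""
    B, C, D, H, W = x.shape
    for b in range(B):
        for c in range(C):
            for i in range(D // 2):
                for j in range(H // 2):
                    for k in range(W // 2):
                        best = x[b, c, 2 * i, 2 * j, 2 * k]
                        bidx = 0
                        p = 0
                        for di in range(2):
                            for dj in range(2):
                                for dk in range(2):
                                    v = x[b, c, 2 * i + di, 2 * j + dj, 2 * k + dk]
                                    if v > best:
                                        best = v
                                        bidx = p
                                    p += 1
                        out[b, c, i, j, k] = best
                        idx[b, c, i, j, k] = bidx


@numba.njit(cache=True, fastmath=True)
def maxpool2_bwd(gy, idx, gx):
    B, C, D2, H2, W2 = gy.shape
    for b in range(B):
        for c in range(C):
            for i in range(D2):
                for j in range(H2):
                    for k in range(W2):
                        p = idx[b, c, i, j, k]
                        di = p // 4
                        dj = (p // 2) % 2
                        dk = p % 2
                        gx[b, c, 2 * i + di, 2 * j + dj, 2 * k + dk] = gy[b, c, i, j, k]


@numba.njit(cache=True, fastmath=True)
def tconv2_fwd(x, W, out):
    """Kernel-2 stride-2 transposed convolution; out pre-filled with bias.

    x: (B, Ci, D, H, W); W: (Ci, Co, 2, 2, 2); out: (B, Co, 2D, 2H, 2W).
    """
    B, Ci, D, H, Wd = x.shape
    Co = W.shape[1]
    for b in range(B):
        for co in range(Co):
            for ci in range(Ci):
                for xx in range(D):
                    for y in range(H):
                        xrow = x[b, ci, xx, y]
                        for dx in range(2):
                            for dy in range(2):
                                orow = out[b, co, 2 * xx + dx, 2 * y + dy]
                                w0 = W[ci, co, dx, dy, 0]
                                w1 = W[ci, co, dx, dy, 1]
                                for z in range(Wd):
                                    v = xrow[z]
                                    orow[2 * z] += w0 * v
                                    orow[2 * z + 1] += w1 * v


@numba.njit(cache=True, fastmath=True)
def tconv2_bwd(x, W, gy, gx, gW):
    """Gradients of tconv2_fwd w.r.t. input and kernel (accumulated)."""
    B, Ci, D, H, Wd = x.shape
    Co = W.shape[1]
    for b in range(B):
        for ci in range(Ci):
            for co in range(Co):
                for xx in range(D):
                    for y in range(H):
                        xrow = x[b, ci, xx, y]
                        grow_x = gx[b, ci, xx, y]
                        for dx in range(2):
                            for dy in range(2):
                                gyrow = gy[b, co, 2 * xx + dx, 2 * y + dy]
                                w0 = W[ci, co, dx, dy, 0]
                                w1 = W[ci, co, dx, dy, 1]
                                a0 = 0.0
                                a1 = 0.0
                                for z in range(Wd):
                                    g0 = gyrow[2 * z]
                                    g1 = gyrow[2 * z + 1]
                                    grow_x[z] += w0 * g0 + w1 * g1
                                    v = xrow[z]
                                    a0 += v * g0
                                    a1 += v * g1
                                gW[ci, co, dx, dy, 0] += a0
                                gW[ci, co, dx, dy, 1] += a1
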