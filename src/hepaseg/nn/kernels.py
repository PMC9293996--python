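"""Numba kernels for valid (unpadded) 3D convolution and its gradients.

Tensors are laid out ``(batch, channel, x, y, z)`` with z contiguous, so the
innermost loops run over the slice axis and vectorize. Valid convolution
only: the output extent is ``input - kernel + 1`` per axis, no padding is
ever applied inside the network.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def conv3d_forward(x, w, b, y):  # pragma: no cover - exercised via Conv3d
    N, Cin, X, Y, Z = x.shape
    Cout, _, kx, ky, kz = w.shape
    _, _, Xo, Yo, Zo = y.shape
    for n in range(N):
        for co in range(Cout):
            for ix in range(Xo):
                for iy in range(Yo):
                    yv = y[n, co, ix, iy]
                    for iz in range(Zo):
                        yv[iz] = b[co]
                    for ci in range(Cin):
                        for dx in range(kx):
                            for dy in range(ky):
                                xr = x[n, ci, ix + dx, iy + dy]
                                for dz in range(kz):
                                    wv = w[co, ci, dx, dy, dz]
                                    for iz in range(Zo):
                                        yv[iz] += wv * xr[iz + dz]


@njit(cache=True, fastmath=True)
def bn_stats(x, mean, var):  # pragma: no cover
    """Per-channel mean/variance over batch and spatial axes (single pass)."""
    N, C, X, Y, Z = x.shape
    m = np.float64(N * X * Y * Z)
    for c in range(C):
        s = np.float64(0.0)
        ss = np.float64(0.0)
        for n in range(N):
            for ix in range(X):
                for iy in range(Y):
                    xr = x[n, c, ix, iy]
                    for iz in range(Z):
                        v = np.float64(xr[iz])
                        s += v
                        ss += v * v
        mu = s / m
        mean[c] = mu
        var[c] = max(ss / m - mu * mu, 0.0)


@njit(cache=True, fastmath=True)
def bn_relu_forward(x, mean, inv, gamma, beta, y):  # pragma: no cover
    """y = max(gamma * (x - mean) * inv + beta, 0), fused per channel."""
    N, C, X, Y, Z = x.shape
    for n in range(N):
        for c in range(C):
            mu = mean[c]
            a = gamma[c] * inv[c]
            b = beta[c] - a * mu
            for ix in range(X):
                for iy in range(Y):
                    xr = x[n, c, ix, iy]
                    yr = y[n, c, ix, iy]
                    for iz in range(Z):
                        v = a * xr[iz] + b
                        yr[iz] = v if v > 0.0 else 0.0


@njit(cache=True, fastmath=True)
def bn_relu_backward_sums(x, y, gy, mean, inv, s1, s2):  # pragma: no cover
    """Per-channel sums of the ReLU-masked gradient: s1 = sum(g),
    s2 = sum(g * xhat); the ReLU mask is y > 0."""
    N, C, X, Y, Z = x.shape
    for c in range(C):
        a1 = np.float64(0.0)
        a2 = np.float64(0.0)
        mu = mean[c]
        iv = inv[c]
        for n in range(N):
            for ix in range(X):
                for iy in range(Y):
                    xr = x[n, c, ix, iy]
                    yr = y[n, c, ix, iy]
                    gr = gy[n, c, ix, iy]
                    for iz in range(Z):
                        if yr[iz] > 0.0:
                            g = np.float64(gr[iz])
                            a1 += g
                            a2 += g * (xr[iz] - mu) * iv
        s1[c] = a1
        s2[c] = a2


@njit(cache=True, fastmath=True)
def bn_relu_backward(x, y, gy, mean, inv, gamma, s1, s2, gx):  # pragma: no cover
    """gx for the fused batch-norm + ReLU layer (batch statistics)."""
    N, C, X, Y, Z = x.shape
    m = np.float64(N * X * Y * Z)
    for n in range(N):
        for c in range(C):
            mu = mean[c]
            iv = inv[c]
            scale = gamma[c] * iv / m
            c1 = np.float32(s1[c])
            c2 = np.float32(s2[c])
            for ix in range(X):
                for iy in range(Y):
                    xr = x[n, c, ix, iy]
                    yr = y[n, c, ix, iy]
                    gr = gy[n, c, ix, iy]
                    go = gx[n, c, ix, iy]
                    for iz in range(Z):
                        g = gr[iz] if yr[iz] > 0.0 else np.float32(0.0)
                        xh = (xr[iz] - mu) * iv
                        go[iz] = scale * (m * g - c1 - xh * c2)


@njit(cache=True, fastmath=True)
def maxpool221_forward(x, y, idx):  # pragma: no cover
    N, C, X2, Y2, Z = y.shape
    for n in range(N):
        for c in range(C):
            for ix in range(X2):
                for iy in range(Y2):
                    r00 = x[n, c, 2 * ix, 2 * iy]
                    r01 = x[n, c, 2 * ix, 2 * iy + 1]
                    r10 = x[n, c, 2 * ix + 1, 2 * iy]
                    r11 = x[n, c, 2 * ix + 1, 2 * iy + 1]
                    yr = y[n, c, ix, iy]
                    ir = idx[n, c, ix, iy]
                    for iz in range(Z):
                        best = r00[iz]
                        k = np.uint8(0)
                        if r01[iz] > best:
                            best = r01[iz]
                            k = np.uint8(1)
                        if r10[iz] > best:
                            best = r10[iz]
                            k = np.uint8(2)
                        if r11[iz] > best:
                            best = r11[iz]
                            k = np.uint8(3)
                        yr[iz] = best
                        ir[iz] = k


@njit(cache=True, fastmath=True)
def maxpool221_backward(gy, idx, gx):  # pragma: no cover
    N, C, X2, Y2, Z = gy.shape
    for n in range(N):
        for c in range(C):
            for ix in range(X2):
                for iy in range(Y2):
                    gr = gy[n, c, ix, iy]
                    ir = idx[n, c, ix, iy]
                    for iz in range(Z):
                        k = ir[iz]
                        gx[n, c, 2 * ix + (k >> 1), 2 * iy + (k & 1), iz] = gr[iz]


@njit(cache=True, fastmath=True)
def conv3d_backward_input(gy, w, gx):  # pragma: no cover
    N, Cout, Xo, Yo, Zo = gy.shape
    _, Cin, kx, ky, kz = w.shape
    for n in range(N):
        for co in range(Cout):
            for ix in range(Xo):
                for iy in range(Yo):
                    gv = gy[n, co, ix, iy]
                    for ci in range(Cin):
                        for dx in range(kx):
                            for dy in range(ky):
                                xr = gx[n, ci, ix + dx, iy + dy]
                                for dz in range(kz):
                                    wv = w[co, ci, dx, dy, dz]
                                    for iz in range(Zo):
                                        xr[iz + dz] += wv * gv[iz]


@njit(cache=True, fastmath=True)
def conv3d_backward_weights(x, gy, gw, gb):  # pragma: no cover
    N, Cin, X, Y, Z = x.shape
    Cout, _, kx, ky, kz = gw.shape
    _, _, Xo, Yo, Zo = gy.shape
    for n in range(N):
        for co in range(Cout):
            for ix in range(Xo):
                for iy in range(Yo):
                    gv = gy[n, co, ix, iy]
                    s = np.float32(0.0)
                    for iz in range(Zo):
                        s += gv[iz]
                    gb[co] += s
                    for ci in range(Cin):
                        for dx in range(kx):
                            for dy in range(ky):
                                xr = x[n, ci, ix + dx, iy + dy]
                                for dz in range(kz):
                                    acc = np.float32(0.0)
                                    for iz in range(Zo):
                                        acc += gv[iz] * xr[iz + dz]
                                    gw[co, ci, dx, dy, dz] += acc
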