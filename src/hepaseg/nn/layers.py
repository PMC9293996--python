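"""Trainable layers with explicit forward/backward passes.

A small, dependency-free layer zoo sufficient for the anisotropic U-Net:
valid 3D convolution, batch normalization, ReLU, dropout, 2x2x1 max pooling
and 2x2x1 transposed convolution. Layers cache what their backward pass
needs; parameters are ``Param`` objects holding value and gradient.

Weight initialization follows Glorot uniform for convolutions (the common
framework default), so differently seeded trainings differ only through
their initialization stream and patch order.
"""

from __future__ import annotations

import numpy as np

from .kernels import (bn_relu_backward, bn_relu_backward_sums, bn_relu_forward,
                      bn_stats, conv3d_backward_input, conv3d_backward_weights,
                      conv3d_forward, maxpool221_backward, maxpool221_forward)


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; layers expose params() and forward/backward."""

    name = "layer"

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class GeometryError(ValueError):
    """A feature map became non-positive (or mis-aligned) at a named layer."""

    def __init__(self, layer: str, detail: str) -> None:
        super().__init__(f"invalid geometry at layer '{layer}': {detail}")
        self.layer = layer


class Conv3d(Layer):
    """Valid convolution with anisotropic kernel, e.g. (3, 3, 1) or (1, 1, 3)."""

    def __init__(self, cin: int, cout: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator, name: str = "conv") -> None:
        self.cin, self.cout, self.kernel = cin, cout, tuple(kernel)
        self.name = name
        k = int(np.prod(self.kernel))
        fan_in, fan_out = cin * k, cout * k
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(cout, cin) + self.kernel)
        self.w = Param(w.astype(np.float32), f"{name}.w")
        self.b = Param(np.zeros(cout, np.float32), f"{name}.b")
        self.needs_input_grad = True
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        out = tuple(s - k + 1 for s, k in zip(spatial, self.kernel))
        if any(o < 1 for o in out):
            raise GeometryError(self.name, f"input {spatial} too small for kernel {self.kernel}")
        return out  # type: ignore[return-value]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise GeometryError(self.name, f"expected {self.cin} channels, got {x.shape[1]}")
        out = self.out_shape(x.shape[2:])
        x = np.ascontiguousarray(x, dtype=np.float32)
        y = np.empty((x.shape[0], self.cout) + out, np.float32)
        conv3d_forward(x, self.w.value, self.b.value, y)
        self._x = x if training else None
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward before training-mode forward"
        gy = np.ascontiguousarray(gy, dtype=np.float32)
        conv3d_backward_weights(self._x, gy, self.w.grad, self.b.grad)
        if not self.needs_input_grad:
            return np.empty(0, np.float32)
        gx = np.zeros_like(self._x)
        conv3d_backward_input(gy, self.w.value, gx)
        return gx


class BatchNormReLU(Layer):
    """Fused per-channel batch normalization followed by ReLU.

    Normalization reduces over batch and spatial axes. Running statistics
    (used in inference mode) are an exponential moving average with momentum
    0.9, so after a few hundred iterations the running estimate tracks the
    batch estimate closely even for short smoke trainings. The fusion with
    ReLU avoids materializing the normalized intermediate; the backward pass
    recomputes it from the cached layer input.
    """

    def __init__(self, channels: int, name: str = "bn",
                 eps: float = 1e-5, momentum: float = 0.9) -> None:
        self.name, self.eps, self.momentum = name, eps, momentum
        self.gamma = Param(np.ones(channels, np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, np.float32), f"{name}.beta")
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if training:
            mean64 = np.empty(x.shape[1], np.float64)
            var64 = np.empty(x.shape[1], np.float64)
            bn_stats(x, mean64, var64)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean64).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var64).astype(np.float32)
            mean = mean64.astype(np.float32)
            inv = (1.0 / np.sqrt(var64 + self.eps)).astype(np.float32)
        else:
            mean = self.running_mean
            inv = (1.0 / np.sqrt(self.running_var.astype(np.float64) + self.eps)
                   ).astype(np.float32)
        y = np.empty_like(x)
        bn_relu_forward(x, mean, inv, self.gamma.value, self.beta.value, y)
        self._cache = (x, y, mean, inv) if training else None
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, y, mean, inv = self._cache  # type: ignore[misc]
        gy = np.ascontiguousarray(gy, dtype=np.float32)
        s1 = np.empty(x.shape[1], np.float64)
        s2 = np.empty(x.shape[1], np.float64)
        bn_relu_backward_sums(x, y, gy, mean, inv, s1, s2)
        self.beta.grad += s1.astype(np.float32)
        self.gamma.grad += s2.astype(np.float32)
        gx = np.empty_like(x)
        bn_relu_backward(x, y, gy, mean, inv, self.gamma.value, s1, s2, gx)
        return gx


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator, name: str = "dropout") -> None:
        self.rate, self.rng, self.name = rate, rng, name
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / np.float32(keep)
        self._mask = mask
        return x * mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gy
        return gy * self._mask


class MaxPool221(Layer):
    """2x2x1 max pooling: halves the in-plane extent, never touches slices."""

    def __init__(self, name: str = "pool") -> None:
        self.name = name
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, C, X, Y, Z = x.shape
        if X % 2 or Y % 2:
            raise GeometryError(self.name, f"in-plane extent {(X, Y)} must be even")
        x = np.ascontiguousarray(x, dtype=np.float32)
        y = np.empty((N, C, X // 2, Y // 2, Z), np.float32)
        idx = np.empty_like(y, dtype=np.uint8)
        maxpool221_forward(x, y, idx)
        if training:
            self._cache = (idx, x.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache  # type: ignore[misc]
        gx = np.zeros(xshape, np.float32)
        maxpool221_backward(np.ascontiguousarray(gy, dtype=np.float32), idx, gx)
        return gx


class ConvTranspose221(Layer):
    """2x2x1 transposed convolution with stride 2x2x1 (in-plane upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 name: str = "up") -> None:
        self.cin, self.cout, self.name = cin, cout, name
        fan_in, fan_out = cin * 4, cout * 4
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(cin, cout, 2, 2))
        self.w = Param(w.astype(np.float32), f"{name}.w")
        self.b = Param(np.zeros(cout, np.float32), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, C, X, Y, Z = x.shape
        y = np.empty((N, self.cout, 2 * X, 2 * Y, Z), np.float32)
        for dx in range(2):
            for dy in range(2):
                # (N,X,Y,Z,cout) <- (N,C,X,Y,Z) x (C,cout)
                t = np.tensordot(x, self.w.value[:, :, dx, dy], axes=([1], [0]))
                y[:, :, dx::2, dy::2, :] = np.moveaxis(t, -1, 1)
        y += self.b.value.reshape(1, -1, 1, 1, 1)
        self._x = x if training else None
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        gx = np.zeros_like(x)
        self.b.grad += gy.sum(axis=(0, 2, 3, 4), dtype=np.float64).astype(np.float32)
        for dx in range(2):
            for dy in range(2):
                gslice = gy[:, :, dx::2, dy::2, :]
                self.w.grad[:, :, dx, dy] += np.tensordot(
                    x, gslice, axes=([0, 2, 3, 4], [0, 2, 3, 4])).astype(np.float32)
                t = np.tensordot(gslice, self.w.value[:, :, dx, dy], axes=([1], [1]))
                gx += np.moveaxis(t, -1, 1)
        return gx


def center_crop(x: np.ndarray, target: tuple[int, int, int], name: str = "crop") -> np.ndarray:
    """Crop the spatial center of ``x`` to the target extent (for skips)."""
    slices = [slice(None), slice(None)]
    for axis, (have, want) in enumerate(zip(x.shape[2:], target)):
        diff = have - want
        if diff < 0 or diff % 2:
            raise GeometryError(name, f"cannot center-crop {have} to {want} on axis {axis}")
        slices.append(slice(diff // 2, diff // 2 + want))
    return x[tuple(slices)]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
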