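"""Minimal NumPy neural-network layer library used by the landmark model.

Every layer implements ``forward(x, train=...)`` and ``backward(gy)`` with
hand-written vector-Jacobian products; parameters are :class:`Param` objects
tagged as domain-shared or domain-specific so the model can be partitioned
and routed per anatomy.  All arithmetic is float32 and fully deterministic
given a seeded ``numpy.random.Generator``.

Conventions: activations have shape ``(B, C, H, W)``; convolutions are
"same"-padded; 3x3 convolutions use im2col + one GEMM, depthwise 3x3
convolutions use nine shifted fused multiply-adds.
"""

from __future__ import annotations

import numpy as np

SHARED = "shared"

F32 = np.float32


class Param:
    """One trainable tensor with its gradient and an ownership tag.

    ``tag`` is either :data:`SHARED` or an integer domain id; ``key`` is a
    structural name that is identical across the per-domain replicas of the
    same site (used when exchanging domain-specific parameters).
    """

    __slots__ = ("key", "tag", "data", "grad")

    def __init__(self, key: str, data: np.ndarray, tag=SHARED):
        self.key = key
        self.tag = tag
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return int(self.data.size)

    def __repr__(self):  # pragma: no cover
        return f"Param({self.key!r}, shape={self.data.shape}, tag={self.tag})"


class Layer:
    """Base class: stateless apart from per-step caches."""

    def params(self):
        return []

    def buffers(self):
        """Non-trainable state (e.g. batch-norm running moments)."""
        return {}

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError


def kaiming_normal(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


# ---------------------------------------------------------------- convolutions


class PointwiseConv(Layer):
    """1x1 convolution (cross-channel mixing), optionally with bias."""

    def __init__(self, rng, c_in, c_out, key, tag=SHARED, bias=True):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(key + ".w", kaiming_normal(rng, (c_out, c_in), c_in), tag)
        self.b = Param(key + ".b", np.zeros(c_out), tag) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        self._xr = x.reshape(b, c, h * w)
        y = np.matmul(self.w.data, self._xr)
        if self.b is not None:
            y += self.b.data[None, :, None]
        self._hw = (h, w)
        return y.reshape(b, self.c_out, h, w)

    def backward(self, gy):
        b = gy.shape[0]
        h, w = self._hw
        gyr = gy.reshape(b, self.c_out, h * w)
        self.w.grad += np.matmul(gyr, self._xr.transpose(0, 2, 1)).sum(axis=0)
        if self.b is not None:
            self.b.grad += gyr.sum(axis=(0, 2))
        gx = np.matmul(self.w.data.T, gyr)
        return gx.reshape(b, self.c_in, h, w)


class DepthwiseConv3x3(Layer):
    """Per-channel (channel-wise) 3x3 convolution, no bias."""

    def __init__(self, rng, c, key, tag=SHARED):
        self.c = c
        self.w = Param(key + ".w", kaiming_normal(rng, (c, 3, 3), 9), tag)

    def params(self):
        return [self.w]

    def forward(self, x, train=False):
        from ._kernels import dw3x3_forward

        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp = xp
        return dw3x3_forward(xp, self.w.data)

    def backward(self, gy):
        from ._kernels import dw3x3_backward

        gx, gw = dw3x3_backward(self._xp, self.w.data, np.ascontiguousarray(gy))
        self.w.grad += gw
        return gx


class Conv3x3(Layer):
    """Standard (optionally dilated) 3x3 convolution via im2col."""

    def __init__(self, rng, c_in, c_out, key, tag=SHARED, dilation=1, bias=True):
        self.c_in, self.c_out, self.d = c_in, c_out, int(dilation)
        self.w = Param(key + ".w", kaiming_normal(rng, (c_out, c_in, 3, 3), 9 * c_in), tag)
        self.b = Param(key + ".b", np.zeros(c_out), tag) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def _offsets(self):
        d = self.d
        return [(i * d, j * d) for i in range(3) for j in range(3)]

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        d = self.d
        xp = np.pad(x, ((0, 0), (0, 0), (d, d), (d, d)))
        cols = np.empty((b, 9 * c, h * w), dtype=F32)
        for t, (di, dj) in enumerate(self._offsets()):
            cols[:, t * c : (t + 1) * c] = xp[:, :, di : di + h, dj : dj + w].reshape(b, c, h * w)
        self._cols = cols
        self._shape = (b, c, h, w)
        wr = self.w.data.transpose(0, 2, 3, 1).reshape(self.c_out, 9 * c)
        self._wr = wr
        y = np.matmul(wr, cols)
        if self.b is not None:
            y += self.b.data[None, :, None]
        return y.reshape(b, self.c_out, h, w)

    def backward(self, gy):
        b, c, h, w = self._shape
        d = self.d
        gyr = gy.reshape(b, self.c_out, h * w)
        gw = np.matmul(gyr, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.w.grad += gw.reshape(self.c_out, 3, 3, c).transpose(0, 3, 1, 2)
        if self.b is not None:
            self.b.grad += gyr.sum(axis=(0, 2))
        gcols = np.matmul(self._wr.T, gyr)  # (b, 9c, hw)
        gxp = np.zeros((b, c, h + 2 * d, w + 2 * d), dtype=F32)
        for t, (di, dj) in enumerate(self._offsets()):
            gxp[:, :, di : di + h, dj : dj + w] += gcols[:, t * c : (t + 1) * c].reshape(b, c, h, w)
        return gxp[:, :, d:-d, d:-d]


# -------------------------------------------------------------- normalization


class BatchNorm2d(Layer):
    def __init__(self, c, key, tag=SHARED, momentum=0.1, eps=1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(key + ".g", np.ones(c), tag)
        self.beta = Param(key + ".b", np.zeros(c), tag)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self._key = key

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {self._key + ".run_mean": self.run_mean, self._key + ".run_var": self.run_var}

    def set_buffers(self, mean, var):
        self.run_mean = np.asarray(mean, dtype=F32).copy()
        self.run_var = np.asarray(var, dtype=F32).copy()

    def forward(self, x, train=False):
        self._train = train
        if train and x.dtype == np.float32:
            from ._kernels import bn_forward_train

            y, xhat, mean, var, invstd = bn_forward_train(
                np.ascontiguousarray(x), self.gamma.data, self.beta.data, F32(self.eps)
            )
            m = self.momentum
            self.run_mean += F32(m) * (mean - self.run_mean)
            self.run_var += F32(m) * (var - self.run_var)
            self._xhat, self._invstd = xhat, invstd
            return y
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.run_mean += m * (mean - self.run_mean)
            self.run_var += m * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._xhat, self._invstd = xhat, invstd
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, gy):
        xhat, invstd = self._xhat, self._invstd
        if self._train and gy.dtype == np.float32 and xhat.dtype == np.float32:
            from ._kernels import bn_backward_train

            gx, ggamma, gbeta = bn_backward_train(
                xhat, invstd, self.gamma.data, np.ascontiguousarray(gy)
            )
            self.gamma.grad += ggamma
            self.beta.grad += gbeta
            return gx
        self.gamma.grad += np.einsum("bchw,bchw->c", gy, xhat, optimize=True)
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None] * gy
        if not self._train:
            return g * invstd[None, :, None, None]
        n = gy.shape[0] * gy.shape[2] * gy.shape[3]
        s1 = g.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return invstd[None, :, None, None] * (g - s1 / n - xhat * s2 / n)


# ---------------------------------------------------------------- activations


class LeakyReLU(Layer):
    def __init__(self, slope=0.1):
        self.slope = slope

    def forward(self, x, train=False):
        from ._kernels import leaky_forward

        if x.dtype == np.float32:
            self._y = leaky_forward(np.ascontiguousarray(x), F32(self.slope))
        else:  # float64 path kept for high-precision gradient checks
            self._y = np.where(x > 0, x, self.slope * x)
        return self._y

    def backward(self, gy):
        from ._kernels import leaky_backward

        if gy.dtype == np.float32 and self._y.dtype == np.float32:
            return leaky_backward(self._y, np.ascontiguousarray(gy), F32(self.slope))
        return np.where(self._y > 0, gy, self.slope * gy)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, gy):
        return np.where(self._mask, gy, F32(0))


class Sigmoid(Layer):
    def forward(self, x, train=False):
        y = 1.0 / (1.0 + np.exp(-x, dtype=F32))
        self._y = y
        return y

    def backward(self, gy):
        y = self._y
        return gy * y * (1.0 - y)


# --------------------------------------------------------------- pool, resize


class MaxPool2x2(Layer):
    """2x2 max pooling; ties go to the first element in scan order."""

    def forward(self, x, train=False):
        from ._kernels import maxpool2x2_forward

        y, idx = maxpool2x2_forward(np.ascontiguousarray(x))
        self._idx = idx
        return y

    def backward(self, gy):
        from ._kernels import maxpool2x2_backward

        return maxpool2x2_backward(self._idx, np.ascontiguousarray(gy))


_RESIZE_CACHE: dict = {}


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic interpolation matrix for 1-D bilinear resize.

    Uses the half-pixel-center convention: output center i maps to input
    coordinate (i + 0.5) * n_in / n_out - 0.5, clamped at the borders.
    """
    key = (n_in, n_out)
    m = _RESIZE_CACHE.get(key)
    if m is None:
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = (src - lo).astype(F32)
        m = np.zeros((n_out, n_in), dtype=F32)
        m[np.arange(n_out), lo] += 1 - frac
        m[np.arange(n_out), hi] += frac
        _RESIZE_CACHE[key] = m
    return m


def resize_bilinear(x: np.ndarray, out_hw) -> np.ndarray:
    """Separable bilinear resize of a (..., H, W) array."""
    h, w = x.shape[-2], x.shape[-1]
    ho, wo = out_hw
    rh = _bilinear_matrix(h, ho)
    rw = _bilinear_matrix(w, wo)
    return np.matmul(np.matmul(rh, x), rw.T)


class Resize(Layer):
    """Bilinear resize to a fixed output size, with exact transpose backward."""

    def __init__(self, out_hw):
        self.out_hw = tuple(out_hw)

    def forward(self, x, train=False):
        self._in_hw = (x.shape[-2], x.shape[-1])
        return resize_bilinear(x, self.out_hw)

    def backward(self, gy):
        h, w = self._in_hw
        rh = _bilinear_matrix(h, self.out_hw[0])
        rw = _bilinear_matrix(w, self.out_hw[1])
        return np.matmul(np.matmul(rh.T, gy), rw)


class UpsampleNearest2x(Layer):
    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        b, c, h, w = gy.shape
        return gy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ------------------------------------------------------------------ optimizer


class Adam:
    """Standard Adam with bias correction; one slot pair per parameter."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data -= F32(lr) * (m / c1) / (np.sqrt(v / c2) + self.eps)
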