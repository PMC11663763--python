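"""Minimal NumPy neural-network engine for small 2D+time convolutional nets.

Layers operate on arrays of shape (batch, channels, t, y, x) in float32 and
expose an explicit ``forward(x) -> (y, cache)`` / ``backward(cache, gy) ->
gx`` pair; parameter gradients accumulate on the layer's ``Param`` objects,
which makes weight sharing trivial — invoking the same layer twice (the two
encoder branches) simply accumulates both contributions.  Convolutions are
evaluated as one BLAS matmul per kernel offset, which is the fastest pure-
NumPy formulation at these sizes.  Everything is deterministic given the
seeds supplied by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv3d", "GroupNorm", "relu", "relu_backward",
           "avgpool2", "avgpool2_backward", "upsample2", "upsample2_backward",
           "ConvBlock", "Adam"]


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)


class Conv3d:
    """3×3×3 (or 1×1×1) convolution over (t, y, x) with 'same' zero padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False):
        assert k in (1, 3)
        self.k = k
        fan_in = cin * k ** 3
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.w = Param(scale * rng.standard_normal((cout, cin, k, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray):
        B, C, T, H, W = x.shape
        cout = self.w.v.shape[0]
        if self.k == 1:
            y = np.matmul(self.w.v[:, :, 0, 0, 0], x.reshape(B, C, -1))
            y = y.reshape(B, cout, T, H, W) + self.b.v[None, :, None, None, None]
            return y, x
        xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        N = T * H * W
        y = np.zeros((B, cout, N), dtype=np.float32)
        for dt in range(3):
            for dh in range(3):
                for dw in range(3):
                    xs = xpad[:, :, dt:dt + T, dh:dh + H, dw:dw + W]
                    y += np.matmul(self.w.v[:, :, dt, dh, dw],
                                   np.ascontiguousarray(xs).reshape(B, C, N))
        y = y.reshape(B, cout, T, H, W) + self.b.v[None, :, None, None, None]
        return y, xpad

    def backward(self, cache, gy: np.ndarray):
        B, cout, T, H, W = gy.shape
        N = T * H * W
        gyr = gy.reshape(B, cout, N)
        self.b.g += gy.sum(axis=(0, 2, 3, 4))
        if self.k == 1:
            x = cache
            C = x.shape[1]
            xr = x.reshape(B, C, N)
            self.w.g[:, :, 0, 0, 0] += np.einsum("bon,bcn->oc", gyr, xr)
            gx = np.matmul(self.w.v[:, :, 0, 0, 0].T, gyr).reshape(B, C, T, H, W)
            return gx
        xpad = cache
        C = xpad.shape[1]
        gxpad = np.zeros_like(xpad)
        for dt in range(3):
            for dh in range(3):
                for dw in range(3):
                    xs = np.ascontiguousarray(
                        xpad[:, :, dt:dt + T, dh:dh + H, dw:dw + W]).reshape(B, C, N)
                    self.w.g[:, :, dt, dh, dw] += np.einsum("bon,bcn->oc", gyr, xs)
                    gxs = np.matmul(self.w.v[:, :, dt, dh, dw].T, gyr)
                    gxpad[:, :, dt:dt + T, dh:dh + H, dw:dw + W] += \
                        gxs.reshape(B, C, T, H, W)
        return gxpad[:, :, 1:-1, 1:-1, 1:-1]


class GroupNorm:
    """Per-sample feature normalization over channel groups (and t, y, x)."""

    def __init__(self, channels: int, groups: int | None = None, eps: float = 1e-5):
        if groups is None:
            groups = next(g for g in (8, 4, 2, 1) if channels % g == 0)
        assert channels % groups == 0
        self.c, self.g_, self.eps = channels, groups, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray):
        B, C, T, H, W = x.shape
        xg = x.reshape(B, self.g_, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(x.shape).astype(np.float32)
        y = xhat * self.gamma.v[None, :, None, None, None] \
            + self.beta.v[None, :, None, None, None]
        return y, (xhat, inv.astype(np.float32), x.shape)

    def backward(self, cache, gy: np.ndarray):
        xhat, inv, shape = cache
        B, C, T, H, W = shape
        self.gamma.g += (gy * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.g += gy.sum(axis=(0, 2, 3, 4))
        dxhat = gy * self.gamma.v[None, :, None, None, None]
        dg = dxhat.reshape(B, self.g_, -1)
        xh = xhat.reshape(B, self.g_, -1)
        m1 = dg.mean(axis=2, keepdims=True)
        m2 = (dg * xh).mean(axis=2, keepdims=True)
        gx = (dg - m1 - xh * m2) * inv
        return gx.reshape(shape).astype(np.float32)


def relu(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(mask: np.ndarray, gy: np.ndarray):
    return gy * mask


def avgpool2(x: np.ndarray):
    """Spatial 2×2 mean pooling; temporal dimension preserved."""
    return 0.25 * (x[..., ::2, ::2] + x[..., 1::2, ::2]
                   + x[..., ::2, 1::2] + x[..., 1::2, 1::2])


def avgpool2_backward(gy: np.ndarray):
    B, C, T, H, W = gy.shape
    gx = np.empty((B, C, T, 2 * H, 2 * W), dtype=gy.dtype)
    q = 0.25 * gy
    gx[..., ::2, ::2] = q
    gx[..., 1::2, ::2] = q
    gx[..., ::2, 1::2] = q
    gx[..., 1::2, 1::2] = q
    return gx


def upsample2(x: np.ndarray):
    """Nearest-neighbour spatial ×2 upsampling."""
    return x.repeat(2, axis=-2).repeat(2, axis=-1)


def upsample2_backward(gy: np.ndarray):
    return (gy[..., ::2, ::2] + gy[..., 1::2, ::2]
            + gy[..., ::2, 1::2] + gy[..., 1::2, 1::2])


class ConvBlock:
    """(Conv3d → GroupNorm → ReLU) × 2."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.c1 = Conv3d(cin, cout, 3, rng)
        self.n1 = GroupNorm(cout)
        self.c2 = Conv3d(cout, cout, 3, rng)
        self.n2 = GroupNorm(cout)

    def params(self):
        return self.c1.params() + self.n1.params() + self.c2.params() + self.n2.params()

    def forward(self, x: np.ndarray):
        h, k1 = self.c1.forward(x)
        h, k2 = self.n1.forward(h)
        h, k3 = relu(h)
        h, k4 = self.c2.forward(h)
        h, k5 = self.n2.forward(h)
        y, k6 = relu(h)
        return y, (k1, k2, k3, k4, k5, k6)

    def backward(self, cache, gy: np.ndarray):
        k1, k2, k3, k4, k5, k6 = cache
        g = relu_backward(k6, gy)
        g = self.n2.backward(k5, g)
        g = self.c2.backward(k4, g)
        g = relu_backward(k3, g)
        g = self.n1.backward(k2, g)
        return self.c1.backward(k1, g)


class Adam:
    """Adaptive-moment gradient descent over a list of Params."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.s = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, s in zip(self.params, self.m, self.s):
            m += (1 - self.b1) * (p.g - m)
            s += (1 - self.b2) * (p.g * p.g - s)
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)
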