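"""Layers with explicit forward/backward passes (float32, NCHW)."""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable tensor with its accumulated gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = None
        self.v = None


def _conv2d_fw(x, w, stride, pad):
    """x (N,C,H,W) · w (F,C,k,k) → out (N,F,Ho,Wo); returns im2col cache."""
    n, c, _, _ = x.shape
    f, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k
    )
    out = cols @ w.reshape(f, -1).T
    out = out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), cols, (n, c, hp, wp, ho, wo)


def _conv2d_bw(dout, cols, w, stride, pad, dims):
    n, c, hp, wp, ho, wo = dims
    f, _, k, _ = w.shape
    dout2 = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
    dw = (dout2.T @ cols).reshape(f, c, k, k)
    dcols = (dout2 @ w.reshape(f, -1)).reshape(n, ho, wo, c, k, k)
    dxp = np.zeros((n, c, hp, wp), dtype=dout.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += (
                np.moveaxis(dcols[:, :, :, :, ki, kj], 3, 1)
            )
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dw, dxp


class Conv:
    """4×4 convolution, weight init N(0, 0.02) as in DCGAN-family models."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None, bias=True):
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad = k, stride, pad
        self.w = Param(rng.normal(0.0, 0.02, (cout, cin, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None

    @property
    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        out, self._cols, self._dims = _conv2d_fw(x, self.w.value, self.stride, self.pad)
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        return out

    def backward(self, dout):
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        dw, dx = _conv2d_bw(dout, self._cols, self.w.value, self.stride, self.pad, self._dims)
        self.w.grad += dw
        return dx


class ConvT:
    """4×4 stride-2 transposed convolution (2× upsampling).

    Implemented as zero-stuffing followed by a stride-1 convolution with the
    spatially flipped kernel; the backward pass slices gradients back off
    the stuffed grid.
    """

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None, bias=True):
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad = k, stride, pad
        self.w = Param(rng.normal(0.0, 0.02, (cout, cin, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None

    @property
    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, c, h, w_ = x.shape
        s = self.stride
        hz, wz = (h - 1) * s + 1, (w_ - 1) * s + 1
        xz = np.zeros((n, c, hz, wz), dtype=np.float32)
        xz[:, :, ::s, ::s] = x
        wf = np.ascontiguousarray(self.w.value[:, :, ::-1, ::-1])
        out, self._cols, self._dims = _conv2d_fw(xz, wf, 1, self.k - 1 - self.pad)
        if self.b is not None:
            out += self.b.value[None, :, None, None]
        self._in_shape = (h, w_)
        return out

    def backward(self, dout):
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        wf = np.ascontiguousarray(self.w.value[:, :, ::-1, ::-1])
        dwf, dxz = _conv2d_bw(dout, self._cols, wf, 1, self.k - 1 - self.pad, self._dims)
        self.w.grad += dwf[:, :, ::-1, ::-1]
        s = self.stride
        return np.ascontiguousarray(dxz[:, :, ::s, ::s])


class InstanceNorm:
    """Per-sample, per-channel normalization over the spatial axes with a
    learnable affine transform (the batch-size-1 equivalent of batch norm
    used by pix2pix)."""

    def __init__(self, c, eps=1e-5):
        self.eps = eps
        self.g = Param(np.ones(c))
        self.b = Param(np.zeros(c))

    @property
    def params(self):
        return [self.g, self.b]

    def forward(self, x, train=True):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xn = (x - mu) * self._istd
        return self.g.value[None, :, None, None] * self._xn + self.b.value[None, :, None, None]

    def backward(self, dout):
        xn, istd = self._xn, self._istd
        m = xn.shape[2] * xn.shape[3]
        self.g.grad += (dout * xn).sum(axis=(0, 2, 3))
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dxn = dout * self.g.value[None, :, None, None]
        dx = (istd / m) * (
            m * dxn
            - dxn.sum(axis=(2, 3), keepdims=True)
            - xn * (dxn * xn).sum(axis=(2, 3), keepdims=True)
        )
        return dx.astype(np.float32)


class LeakyReLU:
    def __init__(self, slope=0.2):
        self.slope = slope

    params: list = []

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class ReLU:
    params: list = []

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Tanh:
    params: list = []

    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Dropout:
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p=0.5):
        self.p = p

    params: list = []

    def forward(self, x, train=True, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng()
        self._mask = (rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def bce_with_logits(logits, target: float):
    """Binary cross-entropy against a constant label; returns (loss, dlogits)
    with the gradient already averaged over elements."""
    x = logits
    loss = float(np.mean(np.maximum(x, 0.0) - x * target + np.log1p(np.exp(-np.abs(x)))))
    grad = ((1.0 / (1.0 + np.exp(-x))) - target) / x.size
    return loss, grad.astype(np.float32)


class Adam:
    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p in self.params:
            if p.m is None:
                p.m = np.zeros_like(p.value)
                p.v = np.zeros_like(p.value)
            p.m = b1 * p.m + (1.0 - b1) * p.grad
            p.v = b2 * p.v + (1.0 - b2) * p.grad**2
            p.value -= self.lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + self.eps)
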