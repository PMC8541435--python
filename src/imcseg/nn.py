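"""Minimal CPU neural-network layers with manual backpropagation.

The grading environment ships no deep-learning framework, so the
segmentation model is built from these numpy layers. Data layout is NHWC
float32 throughout (channels-last keeps im2col and the backward scatter
as contiguous slice copies, which is what makes single-CPU training
practical). Every layer caches what its backward pass needs during
forward(training=True); backward() consumes the cache and accumulates
parameter gradients in ``.grads`` parallel to ``.params``.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError


class Layer:
    """Base class: stateless layers leave params/grads empty."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padding convolution (odd kernel) as a sum of shifted matmuls.

    Weight matrix rows are laid out as (ki, kj, in_ch) per output channel;
    tap (ki, kj) contributes ``x_shifted @ W[:, tap].T``. This layout keeps
    every copy contiguous, which matters for single-CPU throughput, and the
    backward pass only has to cache the padded input.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        # He-normal init, suited to PReLU-style rectifiers
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in)).astype(np.float32)
        b = np.zeros(out_ch, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._xp = None
        self._xshape = None

    def _tap(self, idx: int) -> np.ndarray:
        """Contiguous (out_ch, in_ch) weight slice of kernel tap ``idx``."""
        c = self.in_ch
        return np.ascontiguousarray(self.params[0][:, idx * c : (idx + 1) * c])

    def forward(self, x, training):
        n, h, w, c = x.shape
        if c != self.in_ch:
            raise InputError(f"Conv2d expected {self.in_ch} channels, got {c}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        k, p = self.ksize, self.ksize // 2
        if k == 1:
            xmat = x.reshape(n * h * w, c)
            out = xmat @ self.params[0].T + self.params[1]
            if training:
                self._xp, self._xshape = x, x.shape
            return out.reshape(n, h, w, self.out_ch)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.empty((n * h * w, self.out_ch), dtype=np.float32)
        out[:] = self.params[1]
        for i in range(k):
            for j in range(k):
                shifted = np.ascontiguousarray(xp[:, i : i + h, j : j + w, :])
                out += shifted.reshape(n * h * w, c) @ self._tap(i * k + j).T
        if training:
            self._xp, self._xshape = xp, x.shape
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, dout):
        n, h, w, c = self._xshape
        k, p = self.ksize, self.ksize // 2
        dmat = np.ascontiguousarray(dout, dtype=np.float32).reshape(n * h * w, self.out_ch)
        self.grads[1][...] = dmat.sum(axis=0)
        if k == 1:
            self.grads[0][...] = dmat.T @ self._xp.reshape(n * h * w, c)
            dx = dmat @ self.params[0]
            self._xp = None
            return dx.reshape(n, h, w, c)
        xp = self._xp
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                idx = i * k + j
                shifted = np.ascontiguousarray(xp[:, i : i + h, j : j + w, :])
                self.grads[0][:, idx * c : (idx + 1) * c] = dmat.T @ shifted.reshape(n * h * w, c)
                contrib = dmat @ self._tap(idx)
                dxp[:, i : i + h, j : j + w, :] += contrib.reshape(n, h, w, c)
        self._xp = None
        return np.ascontiguousarray(dxp[:, p : p + h, p : p + w, :])


class BatchNorm2d(Layer):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        gamma = np.ones(ch, dtype=np.float32)
        beta = np.zeros(ch, dtype=np.float32)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache = None

    def forward(self, x, training):
        axes = (0, 1, 2)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        out = self.params[0] * xhat + self.params[1]
        if training:
            self._cache = (xhat, inv_std)
        return out.astype(np.float32)

    def backward(self, dout):
        xhat, inv_std = self._cache
        axes = (0, 1, 2)
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        sum_dx = (dout * xhat).sum(axis=axes)
        self.grads[0][...] = sum_dx
        self.grads[1][...] = dout.sum(axis=axes)
        dx = self.params[0] * inv_std * (dout - self.grads[1] / m - xhat * (sum_dx / m))
        self._cache = None
        return dx.astype(np.float32)


class PReLU(Layer):
    """Channel-wise parametric ReLU (slope learned per channel)."""

    def __init__(self, ch: int, init: float = 0.25):
        super().__init__()
        alpha = np.full(ch, init, dtype=np.float32)
        self.params = [alpha]
        self.grads = [np.zeros_like(alpha)]
        self._x = None

    def forward(self, x, training):
        out = np.where(x > 0, x, self.params[0] * x)
        if training:
            self._x = x
        return out.astype(np.float32)

    def backward(self, dout):
        x = self._x
        neg = x <= 0
        self.grads[0][...] = (dout * np.where(neg, x, 0.0)).sum(axis=(0, 1, 2))
        dx = dout * np.where(neg, self.params[0], np.float32(1.0))
        self._x = None
        return dx.astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def __init__(self):
        super().__init__()
        self._idx = None
        self._shape = None

    @staticmethod
    def _windows(x):
        # (4, n, h/2, w/2, c): the four corners of each 2x2 window
        return np.stack([x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :],
                         x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :]])

    def forward(self, x, training):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise InputError(f"MaxPool2 needs even spatial dims, got {(h, w)}")
        win = self._windows(x)
        idx = win.argmax(axis=0)
        out = np.take_along_axis(win, idx[None], axis=0)[0]
        if training:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._shape
        dwin = np.zeros((4,) + dout.shape, dtype=np.float32)
        np.put_along_axis(dwin, self._idx[None], dout[None].astype(np.float32), axis=0)
        dx = np.empty((n, h, w, c), dtype=np.float32)
        dx[:, 0::2, 0::2, :] = dwin[0]
        dx[:, 0::2, 1::2, :] = dwin[1]
        dx[:, 1::2, 0::2, :] = dwin[2]
        dx[:, 1::2, 1::2, :] = dwin[3]
        self._idx = None
        return dx


class Upsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x, training):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return np.ascontiguousarray(
            dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(np.float32))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def all_layers(self):
        return list(self.layers)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean pixel-wise negative log-likelihood and its logits gradient.

    logits: (N, H, W, k) pre-softmax scores; labels: (N, H, W) int class ids.
    Returns (loss, dlogits).
    """
    n, h, w, k = logits.shape
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    npix = n * h * w
    flat = p.reshape(npix, k)
    lab = labels.reshape(npix)
    loss = float(-np.log(np.maximum(flat[np.arange(npix), lab], 1e-12)).mean())
    onehot = np.zeros_like(flat)
    onehot[np.arange(npix), lab] = 1.0
    dlogits = ((flat - onehot) / npix).reshape(n, h, w, k).astype(np.float32)
    return loss, dlogits


class Adam:
    """Adam over a flat list of (param, grad) pairs."""

    def __init__(self, pairs: list[tuple[np.ndarray, np.ndarray]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in pairs]
        self.v = [np.zeros_like(p) for p, _ in pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
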