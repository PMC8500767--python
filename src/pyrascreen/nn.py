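"""Minimal NumPy neural-network engine.

Implements exactly the layer set the screening backbone needs -- 3x3
convolutions, 2x2 max pooling, x2 nearest/zero-stuffed upsampling, ReLU,
global average pooling, dense layers, a sigmoid squashing and a single-layer
LSTM -- with hand-written reverse-mode gradients and an Adam optimizer.
All layers operate on ``float32`` arrays in ``(N, C, H, W)`` layout (images)
or ``(B, T, D)`` layout (sequences).

Every layer caches what its backward pass needs when called with
``train=True``; ``backward`` must be preceded by such a forward call.
Gradients accumulate into per-parameter buffers until ``zero_grad``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(x):
    """Numerically stable logistic function."""
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class Layer:
    """Base class: a differentiable operation with optional parameters."""

    def params(self):
        """Return a list of (value, gradient) array pairs, updated in place."""
        return []

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded 2-D convolution (odd kernel), He-initialized."""

    def __init__(self, in_channels, out_channels, kernel_size=3, rng=None):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        std = np.sqrt(2.0 / (in_channels * k * k))
        self.w = (rng.standard_normal((out_channels, in_channels, k, k)) * std).astype(DTYPE)
        self.b = np.zeros(out_channels, DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.pad = k // 2
        self._col = None
        self._xshape = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        col = np.ascontiguousarray(col, dtype=DTYPE)
        if train:
            self._col = col
            self._xshape = x.shape
        wm = self.w.reshape(self.w.shape[0], -1)
        y = col @ wm.T + self.b
        return np.ascontiguousarray(y.reshape(n, h, w, -1).transpose(0, 3, 1, 2))

    def backward(self, dy):
        n, co, h, w = dy.shape
        k, p = self.k, self.pad
        c = self._xshape[1]
        dym = np.ascontiguousarray(dy.transpose(0, 2, 3, 1).reshape(-1, co))
        self.dw += (dym.T @ self._col).reshape(self.w.shape)
        self.db += dym.sum(axis=0)
        dcol = (dym @ self.w.reshape(co, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._col = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; even input dims required.

    Ties split the gradient equally between tied positions (a valid
    subgradient; exact ties are measure-zero for continuous inputs).
    """

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 needs even spatial dims, got %dx%d" % (h, w))
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = r.max(axis=(3, 5))
        if train:
            mask = r == y[:, :, :, None, :, None]
            self._mask = mask
            self._counts = mask.sum(axis=(3, 5))
            self._shape = x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        g = (dy / self._counts)[:, :, :, None, :, None]
        return (self._mask * g).reshape(n, c, h, w)


class Upsample2(Layer):
    """x2 upsampling: nearest-neighbour replication or zero stuffing.

    ``mode="zeros"`` places each value at the top-left of its 2x2 block,
    which together with a following convolution realizes a stride-2
    transposed convolution.
    """

    def __init__(self, mode="nearest"):
        if mode not in ("nearest", "zeros"):
            raise ValueError("unknown upsample mode %r" % (mode,))
        self.mode = mode

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if self.mode == "nearest":
            return x.repeat(2, axis=2).repeat(2, axis=3)
        y = np.zeros((n, c, 2 * h, 2 * w), DTYPE)
        y[:, :, ::2, ::2] = x
        return y

    def backward(self, dy):
        n, c, h, w = dy.shape
        if self.mode == "nearest":
            return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
        return np.ascontiguousarray(dy[:, :, ::2, ::2])


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).astype(DTYPE)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        std = np.sqrt(2.0 / d_in)
        self.w = (rng.standard_normal((d_in, d_out)) * std).astype(DTYPE)
        self.b = np.zeros(d_out, DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.w.T


class Sigmoid(Layer):
    def forward(self, x, train=False):
        y = sigmoid(x)
        if train:
            self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class LSTM(Layer):
    """Single-layer LSTM over (B, T, D) sequences, returning (B, T, H).

    Gate order in the packed weight matrices is (input, forget, cell, output);
    the forget-gate bias starts at 1 (standard initialization that keeps early
    gradients flowing).
    """

    def __init__(self, d_in, hidden, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        s = 1.0 / np.sqrt(hidden)
        self.wx = (rng.uniform(-s, s, (d_in, 4 * hidden))).astype(DTYPE)
        self.wh = (rng.uniform(-s, s, (hidden, 4 * hidden))).astype(DTYPE)
        self.b = np.zeros(4 * hidden, DTYPE)
        self.b[hidden:2 * hidden] = 1.0
        self.dwx = np.zeros_like(self.wx)
        self.dwh = np.zeros_like(self.wh)
        self.db = np.zeros_like(self.b)
        self.hidden = hidden

    def params(self):
        return [(self.wx, self.dwx), (self.wh, self.dwh), (self.b, self.db)]

    def forward(self, x, train=False):
        b, t, d = x.shape
        hdim = self.hidden
        h = np.zeros((b, hdim), DTYPE)
        c = np.zeros((b, hdim), DTYPE)
        hs = np.zeros((b, t, hdim), DTYPE)
        cache = []
        for step in range(t):
            a = x[:, step, :] @ self.wx + h @ self.wh + self.b
            i = sigmoid(a[:, :hdim])
            f = sigmoid(a[:, hdim:2 * hdim])
            g = np.tanh(a[:, 2 * hdim:3 * hdim])
            o = sigmoid(a[:, 3 * hdim:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if train:
                cache.append((x[:, step, :], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
            hs[:, step, :] = h
        if train:
            self._cache = cache
            self._xshape = x.shape
        return hs

    def backward(self, dhs):
        b, t, d = self._xshape
        hdim = self.hidden
        dx = np.zeros((b, t, d), DTYPE)
        dh_next = np.zeros((b, hdim), DTYPE)
        dc_next = np.zeros((b, hdim), DTYPE)
        for step in reversed(range(t)):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc = self._cache[step]
            dh = dhs[:, step, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dwx += x_t.T @ da
            self.dwh += h_prev.T @ da
            self.db += da.sum(axis=0)
            dx[:, step, :] = da @ self.wx.T
            dh_next = da @ self.wh.T
        self._cache = None
        return dx


class Adam:
    """Adam over a list of (value, gradient) array pairs, updated in place."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0

    def step(self, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def lr_schedule(epoch, n_epochs, lr_initial, lr_final):
    """Learning rate decayed from lr_initial to lr_final in equal steps per epoch."""
    if n_epochs <= 1:
        return lr_initial
    frac = epoch / (n_epochs - 1)
    return lr_initial + (lr_final - lr_initial) * frac


def numeric_gradient(fn, x, eps=1e-4):
    """Central-difference gradient of scalar fn at x (test utility)."""
    x = x.astype(np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = fn(x)
        x[idx] = orig - eps
        fm = fn(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
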