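"""Minimal numpy layers with explicit backprop for the pair classifier.

Implements exactly what the 2 x 217 x 1 architecture needs: 2-D convolution
(valid, strided, with an optional minimal "short-axis" padding so a 3 x 3
kernel can traverse the height-2 input), max pooling with per-axis window
clipping, softplus, dropout, dense layers, softmax cross-entropy, and Adam.

Array convention: activations are (N, H, W, C); conv weights are
(kh, kw, c_in, c_out).
"""

from __future__ import annotations

import numpy as np


def softplus(x: np.ndarray) -> np.ndarray:
    """ln(1 + e^x), overflow-safe: equals x + ln(1 + e^-x) for large x.

    Preserves floating dtype (the network runs in float32; scalar and integer
    inputs are promoted to float64).
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _pad_amounts(size: int, kernel: int, policy: str) -> tuple[int, int]:
    """Minimal padding so a kernel fits; only the short-axis-same policy pads."""
    if policy == "valid" or size >= kernel:
        return 0, 0
    deficit = kernel - size
    return deficit // 2, deficit - deficit // 2


class Conv2D(Layer):
    """Strided valid convolution after minimal short-axis padding."""

    def __init__(self, kernel: tuple[int, int], c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator, padding_policy: str = "short_axis_same"):
        super().__init__()
        kh, kw = kernel
        self.kh, self.kw, self.stride = kh, kw, stride
        self.policy = padding_policy
        fan_in = kh * kw * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kh, kw, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        ph = sum(_pad_amounts(h, self.kh, self.policy))
        pw = sum(_pad_amounts(w, self.kw, self.policy))
        oh = (h + ph - self.kh) // self.stride + 1
        ow = (w + pw - self.kw) // self.stride + 1
        return oh, ow

    def forward(self, x, train):
        ph = _pad_amounts(x.shape[1], self.kh, self.policy)
        pw = _pad_amounts(x.shape[2], self.kw, self.policy)
        self._pads = (ph, pw)
        if any(ph) or any(pw):
            x = np.pad(x, ((0, 0), ph, pw, (0, 0)))
        n, h, w, c = x.shape
        s = self.stride
        oh = (h - self.kh) // s + 1
        ow = (w - self.kw) // s + 1
        if oh < 1 or ow < 1:
            raise ValueError(f"conv kernel {self.kh}x{self.kw} does not fit input {h}x{w}")
        win = np.lib.stride_tricks.sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        win = win[:, ::s, ::s]                      # (n, oh, ow, c, kh, kw)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, -1)
        Wm = self.W.reshape(-1, self.W.shape[-1])
        y = cols @ Wm + self.b
        self._cache = (x.shape, cols, oh, ow)
        return y.reshape(n, oh, ow, -1)

    def backward(self, dy):
        xshape, cols, oh, ow = self._cache
        n = xshape[0]
        dflat = dy.reshape(n * oh * ow, -1)
        self.grads[0][...] = (cols.T @ dflat).reshape(self.W.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        dx = np.zeros(xshape, dtype=np.float32)
        s = self.stride
        for p in range(self.kh):
            for q in range(self.kw):
                dx[:, p:p + s * oh:s, q:q + s * ow:s, :] += dy @ self.W[p, q].T
        ph, pw = self._pads
        h = xshape[1] - sum(ph)
        w = xshape[2] - sum(pw)
        return dx[:, ph[0]:ph[0] + h, pw[0]:pw[0] + w, :]


class MaxPool2D(Layer):
    """Max pooling whose window is clipped to the input on each axis.

    An axis shorter than the nominal window is pooled with window (and
    stride) 1, i.e. that axis passes through; if both axes clip to 1 the
    layer is the identity.
    """

    def __init__(self, size: int = 2, stride: int = 2):
        super().__init__()
        self.size, self.stride = size, stride

    def _geometry(self, h, w):
        wh, ww = min(self.size, h), min(self.size, w)
        sh = self.stride if wh > 1 else 1
        sw = self.stride if ww > 1 else 1
        oh = (h - wh) // sh + 1
        ow = (w - ww) // sw + 1
        return wh, ww, sh, sw, oh, ow

    def out_shape(self, h, w):
        *_, oh, ow = self._geometry(h, w)
        return oh, ow

    def forward(self, x, train):
        n, h, w, c = x.shape
        wh, ww, sh, sw, oh, ow = self._geometry(h, w)
        win = np.lib.stride_tricks.sliding_window_view(x, (wh, ww), axis=(1, 2))
        flat = np.ascontiguousarray(win[:, ::sh, ::sw]).reshape(n, oh, ow, c, wh * ww)
        self._argmax = flat.argmax(axis=-1)
        self._geom = (x.shape, wh, ww, sh, sw, oh, ow)
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        (xshape, wh, ww, sh, sw, oh, ow) = self._geom
        n, h, w, c = xshape
        dx = np.zeros(xshape, dtype=np.float32)
        bb, ii, jj, cc = np.ix_(np.arange(n), np.arange(oh), np.arange(ow), np.arange(c))
        p = self._argmax // ww
        q = self._argmax % ww
        np.add.at(dx, (bb, ii * sh + p, jj * sw + q, cc), dy)
        return dx


class Softplus(Layer):
    def forward(self, x, train):
        self._x = x
        return softplus(x)

    def backward(self, dy):
        return dy * sigmoid(self._x)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at prediction time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(np.float32)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean numerically-stabilised cross-entropy and gradient w.r.t. logits."""
    n = len(y)
    ls = log_softmax(np.asarray(logits, dtype=np.float64))
    loss = -ls[np.arange(n), y].mean()
    dz = np.exp(ls)
    dz[np.arange(n), y] -= 1.0
    return float(loss), dz / n


class Adam:
    """Adam with optional decoupled weight decay (applied before the update)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # bias-corrected step size; update arrays in place to avoid temporaries
        alpha = lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay and p.ndim > 1:   # decay weights, not biases
                p *= 1.0 - lr * self.weight_decay
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            denom = np.sqrt(v)
            denom += self.eps * np.sqrt(1 - b2 ** self.t)
            p -= alpha * m / denom
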