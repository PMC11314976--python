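"""Minimal feed-forward network layers with explicit backpropagation.

The posture network is small (a few tens of thousands of parameters, tiny
inputs), so the layers here are written directly in numpy: convolutions
via im2col/matmul, pooling with cached argmax, dense layers, inverted
dropout, and a softmax/cross-entropy head.  The optimiser is Adam with
L2 weight decay added to the gradients (Keras-style ``weight_decay``)
plus an optional L1 penalty per layer.

All randomness (initialisation, dropout, batch order) flows through a
seeded ``numpy.random.Generator``, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

#: working precision of the network; float32 halves memory traffic and
#: doubles GEMM throughput at ample precision for a 3-class softmax.
#: Tests that finite-difference the gradients switch this to float64
#: before building layers.
DTYPE = np.float32


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base class: parameterless identity."""

    params: list[np.ndarray]
    grads: list[np.ndarray]
    l1: float = 0.0

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, training=False):
        return x

    def backward(self, dy):
        return dy


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _pad_amounts(n_in: int, k: int, s: int) -> tuple[int, int, int]:
    """'same' padding split (left, right) and output length."""
    n_out = -(-n_in // s)
    total = max((n_out - 1) * s + k - n_in, 0)
    return total // 2, total - total // 2, n_out


class Conv1D(Layer):
    """1-D convolution over (batch, channels, length), ReLU-free."""

    def __init__(self, c_in, c_out, kernel, stride=1, padding="same",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, kernel, stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        self.W = _he_uniform(rng, (c_in * kernel, c_out), c_in * kernel)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        B, C, L = x.shape
        if self.padding == "same":
            pl, pr, n_out = _pad_amounts(L, self.k, self.s)
        else:
            pl = pr = 0
            n_out = (L - self.k) // self.s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        # per-tap strided slices instead of a fancy gather
        cols = np.empty((B, C, self.k, n_out), dtype=DTYPE)
        for j in range(self.k):
            cols[:, :, j, :] = xp[:, :, j:j + (n_out - 1) * self.s + 1:self.s]
        cols = cols.transpose(0, 3, 1, 2).reshape(B, n_out, C * self.k)
        self._cache = (cols, x.shape, (pl, pr), n_out)
        out = cols @ self.W + self.b               # (B, n_out, c_out)
        return out.transpose(0, 2, 1)              # (B, c_out, n_out)

    def backward(self, dy):
        cols, xshape, (pl, pr), n_out = self._cache
        B, C, L = xshape
        dy = dy.transpose(0, 2, 1)                 # (B, n_out, c_out)
        dyf = dy.reshape(B * n_out, self.c_out)
        self.grads[0][...] = cols.reshape(B * n_out, -1).T @ dyf
        self.grads[1][...] = dyf.sum(axis=0)
        dcols = (dy @ self.W.T).reshape(B, n_out, C, self.k)
        dcols = np.ascontiguousarray(dcols.transpose(0, 2, 3, 1))
        dxp = np.zeros((B, C, L + pl + pr), dtype=DTYPE)
        for j in range(self.k):
            dxp[:, :, j:j + (n_out - 1) * self.s + 1:self.s] += dcols[:, :, j, :]
        return dxp[:, :, pl:pl + L]


class Conv2D(Layer):
    """2-D convolution over (batch, channels, height, width)."""

    def __init__(self, c_in, c_out, kernel, stride=(1, 1), padding="same",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kh, self.kw = kernel
        self.sh, self.sw = stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * self.kh * self.kw
        self.W = _he_uniform(rng, (fan_in, c_out), fan_in)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        B, C, H, Wd = x.shape
        if self.padding == "same":
            pt, pb, h_out = _pad_amounts(H, self.kh, self.sh)
            pl, pr, w_out = _pad_amounts(Wd, self.kw, self.sw)
        else:
            pt = pb = pl = pr = 0
            h_out = (H - self.kh) // self.sh + 1
            w_out = (Wd - self.kw) // self.sw + 1
            if h_out < 1 or w_out < 1:
                raise ValueError(
                    f"Conv2D valid kernel ({self.kh},{self.kw}) larger than "
                    f"input {H}x{Wd}")
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        cols = np.empty((B, C, self.kh, self.kw, h_out, w_out), dtype=DTYPE)
        for a in range(self.kh):
            for b in range(self.kw):
                cols[:, :, a, b] = xp[:, :,
                                      a:a + (h_out - 1) * self.sh + 1:self.sh,
                                      b:b + (w_out - 1) * self.sw + 1:self.sw]
        cols = cols.transpose(0, 4, 5, 1, 2, 3).reshape(
            B, h_out * w_out, C * self.kh * self.kw)
        self._cache = (cols, x.shape, (pt, pb, pl, pr), (h_out, w_out))
        out = cols @ self.W + self.b
        return out.reshape(B, h_out, w_out, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, xshape, (pt, pb, pl, pr), (h_out, w_out) = self._cache
        B, C, H, Wd = xshape
        dy = dy.transpose(0, 2, 3, 1).reshape(B, h_out * w_out, self.c_out)
        dyf = dy.reshape(-1, self.c_out)
        self.grads[0][...] = cols.reshape(dyf.shape[0], -1).T @ dyf
        self.grads[1][...] = dyf.sum(axis=0)
        dcols = dy @ self.W.T
        dcols = dcols.reshape(B, h_out, w_out, C, self.kh, self.kw)
        dcols = np.ascontiguousarray(dcols.transpose(0, 3, 4, 5, 1, 2))
        dxp = np.zeros((B, C, H + pt + pb, Wd + pl + pr), dtype=DTYPE)
        for a in range(self.kh):
            for b in range(self.kw):
                dxp[:, :, a:a + (h_out - 1) * self.sh + 1:self.sh,
                    b:b + (w_out - 1) * self.sw + 1:self.sw] += dcols[:, :, a, b]
        return dxp[:, :, pt:pt + H, pl:pl + Wd]


class MaxPool1D(Layer):
    def __init__(self, pool: int, stride: int | None = None):
        super().__init__()
        self.p = pool
        self.s = stride or pool

    def forward(self, x, training=False):
        B, C, L = x.shape
        n_out = (L - self.p) // self.s + 1
        idx = (np.arange(n_out) * self.s)[:, None] + np.arange(self.p)
        win = x[:, :, idx]                          # (B, C, n_out, p)
        arg = win.argmax(axis=-1)
        self._cache = (x.shape, idx, arg)
        return np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        xshape, idx, arg = self._cache
        dx = np.zeros(xshape, dtype=DTYPE)
        starts = idx[:, 0]                          # (n_out,)
        pos = starts[None, None, :] + arg           # (B, C, n_out)
        np.add.at(dx, (np.arange(xshape[0])[:, None, None],
                       np.arange(xshape[1])[None, :, None], pos), dy)
        return dx


class MaxPool2D(Layer):
    def __init__(self, pool=(2, 2), stride=None):
        super().__init__()
        self.ph, self.pw = pool
        self.sh, self.sw = stride or pool

    def forward(self, x, training=False):
        B, C, H, W = x.shape
        h_out = (H - self.ph) // self.sh + 1
        w_out = (W - self.pw) // self.sw + 1
        ih = (np.arange(h_out) * self.sh)[:, None] + np.arange(self.ph)
        iw = (np.arange(w_out) * self.sw)[:, None] + np.arange(self.pw)
        win = x[:, :, ih[:, :, None, None], iw[None, None, :, :]]
        # (B, C, h_out, ph, w_out, pw) -> flatten window dims
        win = win.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, h_out, w_out,
                                                      self.ph * self.pw)
        arg = win.argmax(axis=-1)
        self._cache = (x.shape, (ih, iw), arg, (h_out, w_out))
        return np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        xshape, (ih, iw), arg, (h_out, w_out) = self._cache
        B, C, H, W = xshape
        dx = np.zeros(xshape, dtype=DTYPE)
        ah, aw = arg // self.pw, arg % self.pw
        r0 = (np.arange(h_out) * self.sh)[None, None, :, None]
        c0 = (np.arange(w_out) * self.sw)[None, None, None, :]
        rpos = r0 + ah
        cpos = c0 + aw
        np.add.at(dx, (np.arange(B)[:, None, None, None],
                       np.arange(C)[None, :, None, None], rpos, cpos), dy)
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x, training=False):
        self._n = x.shape[-1]
        return x.mean(axis=-1)

    def backward(self, dy):
        return np.repeat(dy[..., None], self._n, axis=-1) / self._n


class GlobalMaxPool2D(Layer):
    """Adaptive max pool to 1 x 1 (identity safeguard after the final
    valid convolution, which already reduces to a single position)."""

    def forward(self, x, training=False):
        B, C, H, W = x.shape
        flat = x.reshape(B, C, -1)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        B, C, H, W = self._shape
        dx = np.zeros((B, C, H * W), dtype=DTYPE)
        np.put_along_axis(dx, self._arg[..., None], dy[..., None], axis=-1)
        return dx.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng: np.random.Generator | None = None,
                 l1: float = 0.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.W = _he_uniform(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.l1 = l1

    def forward(self, x, training=False):
        self._x = np.asarray(x, dtype=DTYPE)
        return self._x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, onehot: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(p + 1e-12)).sum() / n)
    return loss, ((p - onehot) / n).astype(DTYPE)


class Adam:
    """Adam with additive L2 weight decay and per-layer L1 on request."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7,
                 weight_decay=0.0):
        self.entries = []
        for layer in layers:
            for p, g in zip(layer.params, layer.grads):
                self.entries.append((p, g, np.zeros_like(p), np.zeros_like(p),
                                     layer.l1 if p.ndim > 1 else 0.0))
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v, l1 in self.entries:
            grad = g + self.wd * p
            if l1 > 0:
                grad = grad + l1 * np.sign(p)
            m[...] = self.b1 * m + (1 - self.b1) * grad
            v[...] = self.b2 * v + (1 - self.b2) * grad * grad
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def parameter_count(layers) -> int:
    return int(sum(p.size for layer in layers for p in layer.params))
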