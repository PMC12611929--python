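"""Minimal NumPy neural-network engine (NHWC layout).

Implements exactly the layers the knee-grading classifier needs — 2-D
convolution, batch normalization, ReLU, max/average pooling, dense layers,
dropout, softmax cross-entropy — each with an analytic backward pass and an
Adam optimizer. The conv forward pass is the textbook cross-correlation

    y[i, j] = sum_m sum_n X[i+m, j+n] * W[m, n] + b

and its gradients (the transposed scatter for dX, the input-weighted sum
for dW) are hand-derived and verified against central finite differences in
the test suite.

Parameter-accounting conventions follow the common transfer-learning
bookkeeping: conv kernels, biases, dense weights and batch-norm scale/shift
are trainable; batch-norm running mean and variance are counted as
non-trainable parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Module", "Sequential", "Conv2d", "BatchNorm2d", "ReLU",
    "MaxPool2d", "AvgPool2d", "GlobalAvgPool", "Flatten", "Dense", "Dropout",
    "DenseBlock", "Transition", "softmax", "softmax_cross_entropy", "Adam",
]


class Param:
    """A tensor of learnable (or tracked) parameters."""

    __slots__ = ("value", "grad", "trainable", "l2")

    def __init__(self, value: np.ndarray, trainable: bool = True, l2: float = 0.0):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.l2 = l2

    @property
    def size(self) -> int:
        return int(self.value.size)


class Module:
    """Base class: children are discovered from instance attributes."""

    training: bool = False

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in vars(self).values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for v in vars(self).values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def out_shape(self, in_shape):
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape


def _same_pad(size: int, k: int, s: int) -> tuple[int, int]:
    total = max((int(np.ceil(size / s)) - 1) * s + k - size, 0)
    return total // 2, total - total // 2


class Conv2d(Module):
    """2-D convolution (cross-correlation), NHWC, 'same' or 'valid' padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: str = "same", bias: bool = True, l2: float = 0.0,
                 rng: np.random.Generator | None = None):
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * in_ch
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                       size=(kernel, kernel, in_ch, out_ch)), l2=l2)
        self.bias = Param(np.zeros(out_ch)) if bias else None
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def _pads(self, h, w):
        if self.padding == "same":
            return _same_pad(h, self.kernel, self.stride), _same_pad(w, self.kernel, self.stride)
        return (0, 0), (0, 0)

    def forward(self, x):
        n, h, w, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        (pt, pb), (pl, pr) = self._pads(h, w)
        k, s = self.kernel, self.stride
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if (pt or pb or pl or pr) else x
        hp, wp = xp.shape[1], xp.shape[2]
        if hp < k or wp < k:
            raise ValueError(f"kernel {k} larger than padded input {(hp, wp)}")
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        # shift-accumulate: one (N*Ho*Wo, C) @ (C, O) matmul per kernel offset
        y = np.zeros((n, ho, wo, self.out_ch))
        for i in range(k):
            for j in range(k):
                xs = xp[:, i : i + ho * s : s, j : j + wo * s : s, :]
                y += (xs.reshape(-1, c) @ self.weight.value[i, j]).reshape(n, ho, wo, -1)
        if self.bias is not None:
            y += self.bias.value
        self._cache = (x.shape, xp, (pt, pl), (ho, wo))
        return y

    def backward(self, dy):
        x_shape, xp, (pt, pl), (ho, wo) = self._cache
        n = x_shape[0]
        k, s, c = self.kernel, self.stride, self.in_ch
        dy_flat = dy.reshape(-1, self.out_ch)
        if self.bias is not None:
            self.bias.grad += dy_flat.sum(axis=0)
        dxp = np.zeros(xp.shape)
        for i in range(k):
            for j in range(k):
                xs = xp[:, i : i + ho * s : s, j : j + wo * s : s, :]
                self.weight.grad[i, j] += xs.reshape(-1, c).T @ dy_flat
                dxp[:, i : i + ho * s : s, j : j + wo * s : s, :] += (
                    dy_flat @ self.weight.value[i, j].T
                ).reshape(n, ho, wo, c)
        return dxp[:, pt : pt + x_shape[1], pl : pl + x_shape[2], :]

    def out_shape(self, in_shape):
        h, w, _ = in_shape
        if self.padding == "same":
            ho, wo = int(np.ceil(h / self.stride)), int(np.ceil(w / self.stride))
        else:
            ho = (h - self.kernel) // self.stride + 1
            wo = (w - self.kernel) // self.stride + 1
        return (ho, wo, self.out_ch)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = Param(np.zeros(ch), trainable=False)
        self.running_var = Param(np.ones(ch), trainable=False)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x):
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean.value = m * self.running_mean.value + (1 - m) * mean
            self.running_var.value = m * self.running_var.value + (1 - m) * var
        else:
            mean, var = self.running_mean.value, self.running_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        if self.training:
            dxhat = dy * self.gamma.value
            return inv / m * (m * dxhat - dxhat.sum(axis=axes)
                              - xhat * (dxhat * xhat).sum(axis=axes))
        return dy * self.gamma.value * inv

    def out_shape(self, in_shape):
        return in_shape


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def out_shape(self, in_shape):
        return in_shape


class MaxPool2d(Module):
    def __init__(self, pool: int, stride: int, padding: str = "valid"):
        self.pool, self.stride, self.padding = pool, stride, padding

    def forward(self, x):
        n, h, w, c = x.shape
        k, s = self.pool, self.stride
        if self.padding == "same":
            (pt, pb), (pl, pr) = _same_pad(h, k, s), _same_pad(w, k, s)
        else:
            pt = pb = pl = pr = 0
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        ho, wo = win.shape[1], win.shape[2]
        flat = win.reshape(n, ho, wo, c, k * k)
        self._arg = flat.argmax(axis=-1)
        self._geom = (x.shape, xp.shape, (pt, pl), ho, wo)
        return flat.max(axis=-1)

    def backward(self, dy):
        x_shape, xp_shape, (pt, pl), ho, wo = self._geom
        n, _, _, c = x_shape
        k, s = self.pool, self.stride
        dxp = np.zeros(xp_shape)
        ii, jj = np.divmod(self._arg, k)  # (N, Ho, Wo, C)
        rows = (np.arange(ho)[None, :, None, None] * s + ii)
        cols = (np.arange(wo)[None, None, :, None] * s + jj)
        nn_idx = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, None, None, :]
        np.add.at(dxp, (np.broadcast_to(nn_idx, dy.shape), rows, cols,
                        np.broadcast_to(cc, dy.shape)), dy)
        return dxp[:, pt : pt + x_shape[1], pl : pl + x_shape[2], :]

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if self.padding == "same":
            return (int(np.ceil(h / self.stride)), int(np.ceil(w / self.stride)), c)
        return ((h - self.pool) // self.stride + 1, (w - self.pool) // self.stride + 1, c)


class AvgPool2d(Module):
    """Non-overlapping average pooling (pool == stride, evenly dividing)."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x):
        n, h, w, c = x.shape
        k = self.pool
        if h % k or w % k:
            raise ValueError(f"avg pool {k} does not divide {h}x{w}")
        self._in_shape = x.shape
        return x.reshape(n, h // k, k, w // k, k, c).mean(axis=(2, 4))

    def backward(self, dy):
        n, h, w, c = self._in_shape
        k = self.pool
        return np.broadcast_to(
            dy[:, :, None, :, None, :], (n, h // k, k, w // k, k, c)
        ).reshape(n, h, w, c) / (k * k)

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h // self.pool, w // self.pool, c)


class GlobalAvgPool(Module):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._in_shape
        return np.broadcast_to(dy[:, None, None, :], self._in_shape) / (h * w)

    def out_shape(self, in_shape):
        return (in_shape[2],)


class Flatten(Module):
    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Module):
    """Fully connected layer: y = f(W x + b) with f applied by a later layer."""

    def __init__(self, in_dim: int, out_dim: int, bias: bool = True, l2: float = 0.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim)), l2=l2)
        self.bias = Param(np.zeros(out_dim)) if bias else None
        self.in_dim, self.out_dim = in_dim, out_dim

    def forward(self, x):
        if x.shape[1] != self.in_dim:
            raise ValueError(f"dense expects {self.in_dim} features, got {x.shape[1]}")
        self._x = x
        y = x @ self.weight.value
        return y + self.bias.value if self.bias is not None else y

    def backward(self, dy):
        self.weight.grad += self._x.T @ dy
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value.T

    def out_shape(self, in_shape):
        return (self.out_dim,)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def out_shape(self, in_shape):
        return in_shape


class _DenseLayer(Module):
    """One densely connected layer: BN-ReLU-1x1 conv-BN-ReLU-3x3 conv."""

    def __init__(self, in_ch: int, growth: int, rng):
        self.body = Sequential([
            BatchNorm2d(in_ch), ReLU(),
            Conv2d(in_ch, 4 * growth, 1, bias=False, rng=rng),
            BatchNorm2d(4 * growth), ReLU(),
            Conv2d(4 * growth, growth, 3, padding="same", bias=False, rng=rng),
        ])

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, dy):
        return self.body.backward(dy)

    def out_shape(self, in_shape):
        return self.body.out_shape(in_shape)


class DenseBlock(Module):
    """Concatenative dense block: each layer sees all previous feature maps."""

    def __init__(self, in_ch: int, n_layers: int, growth: int, rng):
        self.growth = growth
        self.layers = [_DenseLayer(in_ch + i * growth, growth, rng) for i in range(n_layers)]
        self.out_ch = in_ch + n_layers * growth

    def forward(self, x):
        for layer in self.layers:
            y = layer.forward(x)
            x = np.concatenate([x, y], axis=-1)
        return x

    def backward(self, dy):
        g = self.growth
        for layer in reversed(self.layers):
            dx, d_new = dy[..., :-g], dy[..., -g:]
            dy = dx + layer.backward(d_new)
        return dy

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (h, w, c + len(self.layers) * self.growth)


class Transition(Module):
    """Compression transition: BN-ReLU-1x1 conv (halve channels)-2x2 avg pool."""

    def __init__(self, in_ch: int, rng):
        self.body = Sequential([
            BatchNorm2d(in_ch), ReLU(),
            Conv2d(in_ch, in_ch // 2, 1, bias=False, rng=rng),
            AvgPool2d(2),
        ])
        self.out_ch = in_ch // 2

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, dy):
        return self.body.backward(dy)

    def out_shape(self, in_shape):
        return self.body.out_shape(in_shape)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy with fused softmax.

    Returns ``(loss, probs, dlogits)`` where ``dlogits`` is the gradient of
    the mean loss with respect to the logits.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(np.clip(probs, 1e-12, 1.0))) / n
    return loss, probs, (probs - onehot) / n


class Adam:
    """Adam optimizer with decoupled-from-nothing classic L2 (added to grads)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if p.l2:
                g = g + 2.0 * p.l2 * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
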