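"""Minimal feed-forward neural networks on numpy.

Provides exactly the pieces the two gait networks need — 2-D/1-D
convolution (im2col + BLAS matmul), leaky ReLU, 2x2 max pooling, batch
normalization, dropout, dense layers — plus softmax cross-entropy, MSE and
binary cross-entropy losses and an Adam optimizer.  All computation is
float32; initialization and dropout draw from explicit generators so
training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (same-padded, stride 1) 2-D convolution over (N, C, H, W)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.k = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Param(rng.normal(0, scale, (out_ch, in_ch * kernel * kernel)))
        self.b = Param(np.zeros(out_ch))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        n, c, h, wd = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
            .reshape(n * h * wd, c * self.k * self.k)
        self._cols, self._shape = cols, (n, c, h, wd)
        out = cols @ self.w.value.T + self.b.value     # (n*h*w, out)
        return np.ascontiguousarray(
            out.reshape(n, h * wd, self.out_ch).transpose(0, 2, 1)) \
            .reshape(n, self.out_ch, h, wd)

    def backward(self, grad):
        n, c, h, wd = self._shape
        d2 = np.ascontiguousarray(
            grad.reshape(n, self.out_ch, h * wd).transpose(0, 2, 1)) \
            .reshape(n * h * wd, self.out_ch)
        self.w.grad = d2.T @ self._cols
        self.b.grad = d2.sum(axis=0)
        # one contiguous reorder, then 9 strided adds (col2im)
        dcols = np.ascontiguousarray(
            (d2 @ self.w.value).reshape(n, h, wd, c, self.k * self.k)
            .transpose(0, 3, 1, 2, 4))
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, wd + 2 * p), F32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + wd] += dcols[..., i * self.k + j]
        self._cols = None
        return dxp[:, :, p:p + h, p:p + wd]


class Conv1D(Layer):
    """Same-padded stride-1 1-D convolution over (N, C, L)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.k = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Param(rng.normal(0, scale, (out_ch, in_ch * kernel)))
        self.b = Param(np.zeros(out_ch))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        n, c, ln = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.k, axis=2)       # (n, c, ln, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)) \
            .reshape(n * ln, c * self.k)
        self._cols, self._shape = cols, (n, c, ln)
        out = cols @ self.w.value.T + self.b.value
        return np.ascontiguousarray(
            out.reshape(n, ln, self.out_ch).transpose(0, 2, 1))

    def backward(self, grad):
        n, c, ln = self._shape
        d2 = np.ascontiguousarray(grad.transpose(0, 2, 1)) \
            .reshape(n * ln, self.out_ch)
        self.w.grad = d2.T @ self._cols
        self.b.grad = d2.sum(axis=0)
        dcols = (d2 @ self.w.value).reshape(n, ln, c, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, ln + 2 * p), F32)
        for i in range(self.k):
            dxp[:, :, i:i + ln] += dcols[:, :, :, i].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, p:p + ln]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; trailing odd rows/cols are cropped."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, :h2 * 2, :w2 * 2]
        r = x.reshape(n, c, h2, 2, w2, 2)
        out = r.max(axis=5).max(axis=3)
        self._mask = (r == out[:, :, :, None, :, None])
        self._shape = (n, c, h, w)
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        g = self._mask * grad[:, :, :, None, :, None]
        out = np.zeros((n, c, h, w), F32)
        out[:, :, :h2 * 2, :w2 * 2] = g.reshape(n, c, h2 * 2, w2 * 2)
        return out


class Dropout(Layer):
    def __init__(self, p: float):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p <= 0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng(0)
        self._mask = (rng.random(x.shape, dtype=F32) >= self.p) \
            .astype(F32) / F32(1 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0, scale, (n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad = grad.T @ self._x
        self.b.grad = grad.sum(axis=0)
        return grad @ self.w.value


class BatchNorm(Layer):
    """Batch normalization over features (2-D input) or channels (3/4-D)."""

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features, F32)
        self.running_var = np.ones(n_features, F32)

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0,) + tuple(range(2, x.ndim))

    def _reshape(self, v, x):
        if x.ndim == 2:
            return v
        return v.reshape((1, -1) + (1,) * (x.ndim - 2))

    def forward(self, x, train=False, rng=None):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._reshape(mean, x)) * self._reshape(inv, x)
        self._cache = (xhat, inv, axes, x.shape)
        return self._reshape(self.gamma.value, x) * xhat \
            + self._reshape(self.beta.value, x)

    def backward(self, grad):
        xhat, inv, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.gamma.grad = (grad * xhat).sum(axis=axes)
        self.beta.grad = grad.sum(axis=axes)
        g = grad * self._reshape(self.gamma.value, grad)
        dxhat_sum = g.sum(axis=axes, keepdims=True)
        dxhat_xhat = (g * xhat).sum(axis=axes, keepdims=True)
        dx = (g - dxhat_sum / m - xhat * dxhat_xhat / m) \
            * self._reshape(inv, grad)
        self._cache = None
        return dx.astype(F32)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False, rng=None):
        x = np.asarray(x, F32)
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad.astype(F32))
        return grad

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- checkpointing ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                out[f"layer{i}_param{j}"] = p.value
            if isinstance(layer, BatchNorm):
                out[f"layer{i}_rmean"] = layer.running_mean
                out[f"layer{i}_rvar"] = layer.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p.value = np.asarray(arrays[f"layer{i}_param{j}"], F32)
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(arrays[f"layer{i}_rmean"], F32)
                layer.running_var = np.asarray(arrays[f"layer{i}_rvar"], F32)

    def save(self, path) -> None:
        np.savez(path, **self.state_arrays())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_arrays(dict(data))


# -- losses -----------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-12))))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(F32)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float(np.mean(diff ** 2)), (2.0 * diff / diff.size).astype(F32)


def bce_with_logits(logits: np.ndarray, target: np.ndarray):
    p = 1.0 / (1.0 + np.exp(-logits))
    loss = float(-np.mean(target * np.log(np.maximum(p, 1e-12))
                          + (1 - target) * np.log(np.maximum(1 - p, 1e-12))))
    return loss, ((p - target) / p.size).astype(F32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= (self.lr * (m / b1t)
                        / (np.sqrt(v / b2t) + self.eps)).astype(F32)
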