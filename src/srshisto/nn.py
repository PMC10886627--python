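"""Minimal CNN building blocks on numpy.

Implements exactly what the tile classifier needs: 3x3 same-padding
convolutions (im2col + BLAS matmul), 2x2 max pooling, ReLU, dense
layers, inverted dropout, a softmax cross-entropy loss with per-class
weights, and Adam.  Arrays are float32, layout ``(batch, H, W, C)``.

Forward passes cache what the backward pass needs; ``backward`` must be
called after ``forward(..., training=True)`` on the same batch.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "InputCenter",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray, sample_weights: np.ndarray):
    """Mean weighted negative log-likelihood and its gradient w.r.t. logits.

    ``sample_weights`` multiplies each sample's loss; with weights
    normalized so their expectation under the class distribution is 1,
    the weighted loss is comparable in magnitude to the unweighted one.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    loss = float(np.mean(sample_weights * nll))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (sample_weights / n)[:, None]
    return loss, grad.astype(np.float32)


class Layer:
    """Base: stateless unless it declares ``params``/``grads`` dicts."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - default
        pass

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (configurable) convolution, stride 1, zero same-padding, He init."""

    def __init__(self, in_channels: int, out_channels: int, ksize: int = 3) -> None:
        super().__init__()
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ksize = ksize
        self.params = {
            "W": np.zeros((in_channels * ksize * ksize, out_channels), dtype=np.float32),
            "b": np.zeros(out_channels, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.in_channels * self.ksize * self.ksize
        std = np.sqrt(2.0 / fan_in)
        self.params["W"][...] = rng.normal(0.0, std, self.params["W"].shape).astype(np.float32)
        self.params["b"][...] = 0.0

    def forward(self, x, training, rng=None):
        b, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        p = self.ksize // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (self.ksize, self.ksize), axis=(1, 2))
        # (b, h, w, c, k, k) -> rows ordered (c, ky, kx), matching W
        cols = np.ascontiguousarray(win).reshape(b * h * w, -1)
        out = cols @ self.params["W"] + self.params["b"]
        if training:
            self._cache = (cols, (b, h, w))
        return out.reshape(b, h, w, self.out_channels)

    def backward(self, dout):
        cols, (b, h, w) = self._cache
        k, cin = self.ksize, self.in_channels
        dflat = dout.reshape(b * h * w, self.out_channels)
        self.grads["W"][...] = cols.T @ dflat
        self.grads["b"][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].T).reshape(b, h, w, cin, k, k)
        p = k // 2
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, cin), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, :, i, j]
        self._cache = None
        return dxp[:, p : p + h, p : p + w, :]


class InputCenter(Layer):
    """Subtract a fixed offset from the inputs (VGG-style mean centering).

    Tiles arrive normalized to [0, 1]; centering them around zero keeps
    the first convolution's pre-activations balanced and speeds up early
    optimization.  No trainable state.
    """

    def __init__(self, offset: float = 0.5) -> None:
        super().__init__()
        self.offset = np.float32(offset)

    def forward(self, x, training, rng=None):
        return x - self.offset

    def backward(self, dout):
        return dout


class ReLU(Layer):
    def forward(self, x, training, rng=None):
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; requires even spatial dimensions."""

    def forward(self, x, training, rng=None):
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {(h, w)}")
        r = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        r = r.reshape(b, h // 2, w // 2, 4, c)
        idx = r.argmax(axis=3)
        out = np.take_along_axis(r, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if training:
            self._cache = (idx, (b, h, w, c))
        return out

    def backward(self, dout):
        idx, (b, h, w, c) = self._cache
        dr = np.zeros((b, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(dr, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = dr.reshape(b, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        self._cache = None
        return dx.reshape(b, h, w, c)


class Flatten(Layer):
    def forward(self, x, training, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.params = {
            "W": np.zeros((in_features, out_features), dtype=np.float32),
            "b": np.zeros(out_features, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def init(self, rng: np.random.Generator) -> None:
        std = np.sqrt(2.0 / self.in_features)
        self.params["W"][...] = rng.normal(0.0, std, self.params["W"].shape).astype(np.float32)
        self.params["b"][...] = 0.0

    def forward(self, x, training, rng=None):
        if training:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        self._x = None
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, training, rng=None):
        if not training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sequential:
    """A plain layer stack with seeded initialization."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def init(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init(rng)

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                yield f"layer{li}.{name}", arr, layer.grads[name]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: arr.copy() for name, arr, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, arr, _ in self.parameters():
            arr[...] = state[name]


class Adam:
    """Adam optimizer over a Sequential's parameters."""

    def __init__(self, model: Sequential, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(arr) for name, arr, _ in model.parameters()}
        self.v = {name: np.zeros_like(arr) for name, arr, _ in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, arr, grad in self.model.parameters():
            m = self.m[name]
            v = self.v[name]
            m[...] = b1 * m + (1 - b1) * grad
            v[...] = b2 * v + (1 - b2) * grad * grad
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
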