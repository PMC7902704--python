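"""Minimal NumPy neural-network engine (NHWC, float32).

Implements exactly the pieces the classifier needs: 2D convolution
(im2col + GEMM, stride 1, same/valid padding), max pooling, inverted
dropout, dense layers, ReLU, softmax cross-entropy, and Adam.  Gradients
are computed layer by layer with cached forward intermediates.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "MaxPool2D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=-1, keepdims=True)
    logsum = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsum
    n = logits.shape[0]
    loss = float(-(onehot * logp).sum() / n)
    grad = (np.exp(logp) - onehot) / n
    return loss, grad.astype(np.float32)


class Layer:
    """Base layer: stateless unless it owns parameters."""

    trainable = False

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        raise NotImplementedError

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p, _ in self.params_grads())


class Conv2D(Layer):
    """3x3-style convolution, stride 1, optional fused ReLU."""

    trainable = True
    type_name = "conv2d"

    def __init__(
        self,
        filters: int,
        kernel: int = 3,
        padding: str = "same",
        activation: str | None = "relu",
    ):
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.filters = filters
        self.kernel = kernel
        self.padding = padding
        self.activation = activation
        self.w: np.ndarray | None = None

    def build(self, input_shape, rng):
        h, w, c = input_shape
        k = self.kernel
        self.pad = (k - 1) // 2 if self.padding == "same" else 0
        ho, wo = h + 2 * self.pad - k + 1, w + 2 * self.pad - k + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"feature map {input_shape} too small for {k}x{k} conv")
        fan_in = k * k * c
        std = np.sqrt(2.0 / fan_in) if self.activation == "relu" else np.sqrt(1.0 / fan_in)
        self.w = rng.normal(0.0, std, size=(fan_in, self.filters)).astype(np.float32)
        self.b = np.zeros(self.filters, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.in_shape = (h, w, c)
        self.out_shape = (ho, wo, self.filters)
        return self.out_shape

    def forward(self, x, train, rng):
        k = self.kernel
        h, w, c = self.in_shape
        if self.pad:
            x = np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad), (0, 0)))
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, ho, wo, c, k, k)
        ho, wo = win.shape[1], win.shape[2]
        col = win.transpose(0, 1, 2, 4, 5, 3).reshape(-1, k * k * c)
        col = np.ascontiguousarray(col, dtype=np.float32)
        out = col @ self.w + self.b
        out = out.reshape(x.shape[0], ho, wo, self.filters)
        if self.activation == "relu":
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        self._col = col
        self._n = x.shape[0]
        return out

    def backward(self, dout):
        if self.activation == "relu":
            dout = np.where(self._mask, dout, 0.0)
        ho, wo, f = self.out_shape
        dflat = dout.reshape(-1, f).astype(np.float32)
        self.dw[...] = self._col.T @ dflat
        self.db[...] = dflat.sum(axis=0)
        dcol = dflat @ self.w.T
        k = self.kernel
        h, w, c = self.in_shape
        n = self._n
        dcol = dcol.reshape(n, ho, wo, k, k, c)
        dxp = np.zeros((n, h + 2 * self.pad, w + 2 * self.pad, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + ho, j : j + wo, :] += dcol[:, :, :, i, j, :]
        self._col = None
        if self.pad:
            return dxp[:, self.pad : -self.pad, self.pad : -self.pad, :]
        return dxp

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class MaxPool2D(Layer):
    """Max pooling with square window; stride defaults to the window size."""

    type_name = "maxpool2d"

    def __init__(self, pool: int = 2, stride: int | None = None):
        self.pool = pool
        self.stride = stride if stride is not None else pool

    def build(self, input_shape, rng):
        h, w, c = input_shape
        p, s = self.pool, self.stride
        ho = (h - p) // s + 1
        wo = (w - p) // s + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"feature map {input_shape} too small for {p}x{p} pooling")
        self.in_shape = input_shape
        self.out_shape = (ho, wo, c)
        return self.out_shape

    def _tiles(self, x):
        """Disjoint p x p tile slices (views, no copies); only for stride == pool."""
        p = self.pool
        ho, wo, _ = self.out_shape
        return [
            x[:, i : ho * p : p, j : wo * p : p, :]
            for i in range(p)
            for j in range(p)
        ]

    def forward(self, x, train, rng):
        p, s = self.pool, self.stride
        ho, wo, c = self.out_shape
        self._n = x.shape[0]
        if p == s:
            self._x = x
            parts = self._tiles(x)
            out = parts[0].copy()
            for part in parts[1:]:
                np.maximum(out, part, out=out)
            self._out = out
            return out
        win = sliding_window_view(x, (p, p), axis=(1, 2))[:, ::s, ::s]
        win = win.reshape(self._n, ho, wo, c, p * p)
        self._amax = win.argmax(axis=-1)
        return np.take_along_axis(win, self._amax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        p, s = self.pool, self.stride
        ho, wo, c = self.out_shape
        h, w, _ = self.in_shape
        n = self._n
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        if p == s:
            # route each gradient to the first maximal element of its tile
            taken = np.zeros(dout.shape, dtype=bool)
            src = self._tiles(self._x)
            dst = self._tiles(dx)
            for x_tile, dx_tile in zip(src, dst):
                hit = (x_tile == self._out) & ~taken
                dx_tile[...] = np.where(hit, dout, 0.0)
                taken |= hit
            self._x = self._out = None
            return dx
        a = self._amax
        ni, hi, wi, ci = np.indices(a.shape, sparse=False)
        r = hi * s + a // p
        col = wi * s + a % p
        np.add.at(dx, (ni, r, col, ci), dout)
        return dx


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    type_name = "dropout"

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def build(self, input_shape, rng):
        self.out_shape = input_shape
        return input_shape

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    type_name = "flatten"

    def build(self, input_shape, rng):
        self.in_shape = input_shape
        self.out_shape = (int(np.prod(input_shape)),)
        return self.out_shape

    def forward(self, x, train, rng):
        self._n = x.shape[0]
        return x.reshape(self._n, -1)

    def backward(self, dout):
        return dout.reshape(self._n, *self.in_shape)


class Dense(Layer):
    """Fully connected layer; 'softmax' activation is applied by the loss /
    predict path, so forward emits logits for it."""

    trainable = True
    type_name = "dense"

    def __init__(self, units: int, activation: str | None = None):
        self.units = units
        self.activation = activation

    def build(self, input_shape, rng):
        (d,) = input_shape
        std = np.sqrt(2.0 / d) if self.activation == "relu" else np.sqrt(1.0 / d)
        self.w = rng.normal(0.0, std, size=(d, self.units)).astype(np.float32)
        self.b = np.zeros(self.units, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.out_shape = (self.units,)
        return self.out_shape

    def forward(self, x, train, rng):
        self._x = x
        out = x @ self.w + self.b
        if self.activation == "relu":
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        return out

    def backward(self, dout):
        if self.activation == "relu":
            dout = np.where(self._mask, dout, 0.0)
        dout = dout.astype(np.float32)
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Sequential:
    """A plain layer stack with logits output and a machine-readable summary."""

    def __init__(self, layers: list[Layer], input_shape: tuple, seed: int = 0):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, rng)
        self.output_shape = shape

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if tuple(x.shape[1:]) != self.input_shape:
            raise ValueError(
                f"input shape {tuple(x.shape[1:])} != expected {self.input_shape}"
            )
        if rng is None:
            rng = np.random.default_rng(0)
        out = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params_grads())
        return out

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def summary(self) -> list[dict]:
        rows = []
        for layer in self.layers:
            row = {
                "type": layer.type_name,
                "output_shape": tuple(layer.out_shape),
                "n_params": layer.n_params,
            }
            if isinstance(layer, Conv2D):
                row["filters"] = layer.filters
            if isinstance(layer, Dense):
                row["units"] = layer.units
                row["activation"] = layer.activation
            rows.append(row)
        return rows

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params_grads()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params_grads()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for (p, _), w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != {p.shape}")
            p[...] = w


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(
        self,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params_grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p, _ in params_grads]
            self._v = [np.zeros_like(p) for p, _ in params_grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for (p, g), m, v in zip(params_grads, self._m, self._v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
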