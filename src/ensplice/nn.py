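"""Minimal NumPy neural-network engine.

Implements exactly the layer vocabulary the sub-model presets need —
Conv1D (stride 1, "same" padding, ReLU), MaxPooling1D, Flatten, Dropout,
Dense — plus the Adam optimizer with a pluggable learning-rate schedule and
binary cross-entropy over a two-unit sigmoid head.  Everything is float32
and deterministic given the seeds supplied by the caller.
"""

from __future__ import annotations

import numpy as np

from .errors import ArchitectureError, InputShapeError

_DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


def random_normal(rng: np.random.Generator, shape, fan_in, fan_out):
    return (rng.normal(0.0, 0.05, size=shape)).astype(_DTYPE)


_INITIALIZERS = {"glorot_uniform": glorot_uniform, "random_normal": random_normal}


class Layer:
    """Base layer: stateless unless it owns parameters."""

    params: list[np.ndarray]
    grads: list[np.ndarray]
    l2: float = 0.0

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        return input_shape

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution, stride 1, "same" padding, ReLU activation."""

    def __init__(self, filters: int, kernel_size: int, initializer="glorot_uniform"):
        super().__init__()
        if filters < 1 or kernel_size < 1:
            raise ArchitectureError("filters and kernel_size must be positive")
        self.filters = filters
        self.kernel_size = kernel_size
        self.initializer = initializer

    def build(self, input_shape, rng):
        length, channels = input_shape
        k, f = self.kernel_size, self.filters
        init = _INITIALIZERS[self.initializer]
        # weight laid out (k, C, F) so forward is k shifted matmuls
        self.w = init(rng, (k, channels, f), fan_in=k * channels, fan_out=k * f)
        self.b = np.zeros(f, dtype=_DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._pad_left = (k - 1) // 2
        self._pad_right = k - 1 - self._pad_left
        return (length, f)

    def forward(self, x, training=False, rng=None):
        n, length, _ = x.shape
        xp = np.pad(x, ((0, 0), (self._pad_left, self._pad_right), (0, 0)))
        z = np.broadcast_to(self.b, (n, length, self.filters)).copy()
        for i in range(self.kernel_size):
            z += xp[:, i : i + length, :] @ self.w[i]
        self._xp = xp if training else None
        self._mask = z > 0
        return np.where(self._mask, z, 0.0)

    def backward(self, dout):
        dz = np.where(self._mask, dout, 0.0).astype(_DTYPE)
        n, length, _ = dz.shape
        dxp = np.zeros_like(self._xp)
        for i in range(self.kernel_size):
            x_slice = self._xp[:, i : i + length, :]
            self.grads[0][i] = np.tensordot(x_slice, dz, axes=([0, 1], [0, 1]))
            dxp[:, i : i + length, :] += dz @ self.w[i].T
        self.grads[1][...] = dz.sum(axis=(0, 1))
        self._xp = None
        end = dxp.shape[1] - self._pad_right
        return dxp[:, self._pad_left : end, :]


class MaxPooling1D(Layer):
    """Max pooling with stride equal to pool size, remainder truncated."""

    def __init__(self, pool_size: int):
        super().__init__()
        if pool_size < 1:
            raise ArchitectureError("pool_size must be positive")
        self.pool_size = pool_size

    def build(self, input_shape, rng):
        length, channels = input_shape
        out_len = length // self.pool_size
        if out_len == 0:
            raise ArchitectureError(
                f"pool width {self.pool_size} collapses length {length} to 0"
            )
        self._out_len = out_len
        return (out_len, channels)

    def forward(self, x, training=False, rng=None):
        p, out_len = self.pool_size, self._out_len
        n, _, c = x.shape
        win = x[:, : out_len * p, :].reshape(n, out_len, p, c)
        self._argmax = win.argmax(axis=2) if training else None
        self._in_shape = x.shape
        return win.max(axis=2)

    def backward(self, dout):
        p, out_len = self.pool_size, self._out_len
        n, length, c = self._in_shape
        dwin = np.zeros((n, out_len, p, c), dtype=_DTYPE)
        np.put_along_axis(dwin, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=_DTYPE)
        dx[:, : out_len * p, :] = dwin.reshape(n, out_len * p, c)
        return dx


class Flatten(Layer):
    def build(self, input_shape, rng):
        self._in_shape = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, training=False, rng=None):
        self._n = x.shape[0]
        return x.reshape(self._n, -1)

    def backward(self, dout):
        return dout.reshape((self._n, *self._in_shape))


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 < rate < 1.0:
            raise ArchitectureError("dropout rate must lie in (0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, units, activation="relu", l2=0.0, initializer="glorot_uniform"):
        super().__init__()
        if units < 1:
            raise ArchitectureError("units must be positive")
        if activation not in ("relu", "sigmoid", "linear"):
            raise ArchitectureError(f"unsupported activation {activation!r}")
        self.units = units
        self.activation = activation
        self.l2 = float(l2)
        self.initializer = initializer

    def build(self, input_shape, rng):
        (dim,) = input_shape
        init = _INITIALIZERS[self.initializer]
        self.w = init(rng, (dim, self.units), fan_in=dim, fan_out=self.units)
        self.b = np.zeros(self.units, dtype=_DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        return (self.units,)

    def forward(self, x, training=False, rng=None):
        z = x @ self.w + self.b
        self._x = x if training else None
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        if self.activation == "sigmoid":
            self._a = 1.0 / (1.0 + np.exp(-z))
            return self._a
        return z

    def backward(self, dout):
        if self.activation == "relu":
            dz = np.where(self._mask, dout, 0.0).astype(_DTYPE)
        elif self.activation == "sigmoid":
            dz = (dout * self._a * (1.0 - self._a)).astype(_DTYPE)
        else:
            dz = dout
        self.grads[0][...] = self._x.T @ dz
        if self.l2 > 0.0:
            self.grads[0] += 2.0 * self.l2 * self.w
        self.grads[1][...] = dz.sum(axis=0)
        dx = dz @ self.w.T
        self._x = None
        return dx


class Adam:
    """Adam with a callable learning-rate schedule evaluated per update step."""

    def __init__(self, schedule, beta1=0.9, beta2=0.999, eps=1e-7):
        self.schedule = schedule
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.step = 0
        self._m = None
        self._v = None

    def update(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        lr = self.schedule(self.step)
        self.step += 1
        t = self.step
        b1, b2 = self.beta1, self.beta2
        corr = lr * np.sqrt(1.0 - b2**t) / (1.0 - b1**t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            p -= corr * m / (np.sqrt(v) + self.eps)


class Network:
    """An ordered layer stack with a sigmoid multi-unit head trained by BCE."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, int], seed: int = 0):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, rng)
        self.output_shape = shape

    # -- parameter access -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w

    # -- forward / backward ----------------------------------------------
    def forward(self, x, training=False, rng=None):
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise InputShapeError(
                f"expected input of shape (N, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {x.shape}"
            )
        out = np.asarray(x, dtype=_DTYPE)
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def l2_penalty(self) -> float:
        return float(
            sum(
                layer.l2 * float(np.square(layer.params[0]).sum())
                for layer in self.layers
                if layer.l2 > 0.0 and layer.params
            )
        )

    def predict_proba(self, x, batch_size: int = 512) -> np.ndarray:
        outs = [
            self.forward(x[i : i + batch_size])
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0) if outs else np.zeros((0, *self.output_shape))


def bce_loss(activations: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy over all units and examples."""
    a = np.clip(activations.astype(np.float64), 1e-7, 1.0 - 1e-7)
    return float(-np.mean(targets * np.log(a) + (1.0 - targets) * np.log(1.0 - a)))


def bce_grad(activations: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Gradient of mean BCE w.r.t. the sigmoid-head activations."""
    a = np.clip(activations.astype(np.float64), 1e-7, 1.0 - 1e-7)
    g = (a - targets) / (a * (1.0 - a)) / targets.size
    return g.astype(_DTYPE)
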