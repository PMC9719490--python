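"""A small, dependency-free feed-forward network engine in NumPy.

Implements exactly what the azimuth regressor needs: same-padded 2D
convolution (im2col matmul), 2x2 max pooling, ReLU, dense layers, a bounded
tanh output head, and minibatch SGD with momentum, L2 weight decay and
global-norm gradient clipping.  Everything is float32 by default, explicitly
seeded, and single-threaded-deterministic; gradients are verified against
finite differences in the test suite.

Layers follow a minimal protocol: ``forward(x)`` caches what backward needs,
``backward(dout)`` returns the input gradient and stores parameter
gradients, ``params()`` yields mutable parameter slots.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "MaxPool2",
    "ReLU",
    "Flatten",
    "Dense",
    "BoundedHead",
    "Sequential",
    "SGD",
]


class Param:
    """One learnable tensor with its gradient and a weight-decay flag."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay


class Layer:
    name: str = ""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, H, W, C) zero-padded 'same' patches -> (B*H*W, k*k*C)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B, H, W, C, k, k)
    B, H, W = x.shape[:3]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B * H * W, k * k * x.shape[3])
    return np.ascontiguousarray(cols)


class Conv2D(Layer):
    """Same-padded stride-1 convolution with square odd kernels."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, dtype=np.float32):
        assert kernel % 2 == 1
        fan_in = kernel * kernel * c_in
        scale = np.sqrt(2.0 / fan_in)
        self.k = kernel
        self.W = Param(rng.normal(0.0, scale, size=(kernel, kernel, c_in, c_out)).astype(dtype), decay=True)
        self.b = Param(np.zeros(c_out, dtype=dtype), decay=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        B, H, W, _ = x.shape
        c_out = self.W.value.shape[3]
        out = self._cols @ self.W.value.reshape(-1, c_out) + self.b.value
        return out.reshape(B, H, W, c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, c_in = self._shape
        c_out = dout.shape[3]
        dflat = dout.reshape(-1, c_out)
        self.W.grad = (self._cols.T @ dflat).reshape(self.W.value.shape)
        self.b.grad = dflat.sum(axis=0)
        # dx = same-correlation of dout with the spatially flipped, channel-swapped kernel
        Wf = self.W.value[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, c_in)
        cols = _im2col(dout, self.k)
        dx = (cols @ Wf).reshape(B, H, W, c_in)
        self._cols = None
        return dx

    def params(self) -> list[Param]:
        return [self.W, self.b]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        h2, w2 = H // 2, W // 2
        xc = x[:, : 2 * h2, : 2 * w2]
        self._in_shape = x.shape
        win = xc.reshape(B, h2, 2, w2, 2, C).transpose(0, 1, 3, 2, 4, 5).reshape(B, h2, w2, 4, C)
        self._idx = win.argmax(axis=3)
        return np.take_along_axis(win, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._in_shape
        h2, w2 = H // 2, W // 2
        grid = np.zeros((B, h2, w2, 4, C), dtype=dout.dtype)
        np.put_along_axis(grid, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : 2 * h2, : 2 * w2] = (
            grid.reshape(B, h2, w2, 2, 2, C).transpose(0, 1, 3, 2, 4, 5).reshape(B, 2 * h2, 2 * w2, C)
        )
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)).astype(dtype), decay=True)
        self.b = Param(np.zeros(n_out, dtype=dtype), decay=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad = self._x.T @ dout
        self.b.grad = dout.sum(axis=0)
        dx = dout @ self.W.value.T
        self._x = None
        return dx

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BoundedHead(Layer):
    """y = scale * tanh(z / temperature): a scalar squashed to [-scale, scale].

    With temperature == scale the map is near-identity for |z| << scale, so
    the head behaves linearly in degrees over most of its range while
    guaranteeing the output bound.
    """

    def __init__(self, scale: float = 180.0, temperature: float = 180.0):
        self.scale = scale
        self.temperature = temperature

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = np.tanh(x / self.temperature)
        return self.scale * self._t

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (self.scale / self.temperature) * (1.0 - self._t**2)


class Sequential:
    """An ordered stack of layers with optional named activation taps."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.named_layers = layers

    def forward(self, x: np.ndarray, collect: tuple[str, ...] = ()) -> np.ndarray | tuple:
        taps = {}
        for name, layer in self.named_layers:
            x = layer.forward(x)
            if name in collect:
                taps[name] = x
        return (x, taps) if collect else x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.named_layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[Param]:
        out: list[Param] = []
        for _, layer in self.named_layers:
            out.extend(layer.params())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (name, layer) in enumerate(self.named_layers):
            for j, p in enumerate(layer.params()):
                out[f"{i:02d}_{name}_{j}"] = p.value
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, (name, layer) in enumerate(self.named_layers):
            for j, p in enumerate(layer.params()):
                p.value[...] = state[f"{i:02d}_{name}_{j}"]


class SGD:
    """Minibatch gradient descent with momentum, L2 decay on weights (the
    gradient of the loss's ``l2 * sum(w**2)`` term), global-norm gradient
    clipping, and optional per-parameter RMSProp scaling.

    With ``rmsprop=True`` each gradient is divided by the square root of an
    exponential moving average of its square before the momentum update,
    which equalises step sizes across layers and makes runs far less
    sensitive to the raw gradient scale of this loss.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 l2: float = 1e-4, clip_norm: float | None = 10.0,
                 rmsprop: bool = False, rms_decay: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.l2 = l2
        self.clip_norm = clip_norm
        self.rmsprop = rmsprop
        self.rms_decay = rms_decay
        self.eps = eps
        self._vel = [np.zeros_like(p.value) for p in params]
        self._sq = [np.zeros_like(p.value) for p in params] if rmsprop else None

    def step(self) -> None:
        grads = []
        for p in self.params:
            g = p.grad
            if p.decay and self.l2:
                g = g + 2.0 * self.l2 * p.value
            grads.append(g)
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        if self.rmsprop:
            scaled = []
            for sq, g in zip(self._sq, grads):
                sq *= self.rms_decay
                sq += (1.0 - self.rms_decay) * g * g
                scaled.append(g / (np.sqrt(sq) + self.eps))
            grads = scaled
        for p, v, g in zip(self.params, self._vel, grads):
            v *= self.momentum
            v -= self.lr * g.astype(v.dtype)
            p.value += v
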