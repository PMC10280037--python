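"""Minimal 1-D convolutional network engine (numpy, explicit backprop).

Implements exactly the layer set needed for a ResNet-style 1-D encoder:
convolution, batch normalization, ReLU, max/global-average pooling, fully
connected layers, dropout, residual blocks, and an Adam optimizer.  Arrays
are ``float64`` throughout and shaped ``(batch, channels, length)``.

Every layer exposes ``forward(x, train)`` / ``backward(dy)`` and dictionaries
``params`` / ``grads`` keyed by parameter name, so a model is a tree of layers
whose flattened state dict can be saved, loaded and hashed.
"""

from __future__ import annotations

import hashlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv1d", "BatchNorm1d", "ReLU", "MaxPool1d", "GlobalAvgPool",
    "Linear", "Dropout", "Sequential", "ResidualBlock", "BottleneckBlock",
    "Adam", "collect_state", "load_state", "state_hash", "count_parameters",
]


class Layer:
    """Base layer: stateless unless it declares ``params``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trainable state

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def children(self) -> list["Layer"]:
        return []

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0
        for c in self.children():
            c.zero_grad()


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Layer):
    """1-D convolution with 'same' padding and integer stride, no bias.

    Bias is omitted because every convolution is followed by a batch
    normalization whose shift parameter subsumes it.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size < 1 or kernel_size % 2 == 0 and kernel_size != 1:
            # even kernels break symmetric 'same' padding
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.pad = (kernel_size - 1) // 2
        self.params["w"] = _he_init(
            rng, (out_channels, in_channels, kernel_size), in_channels * kernel_size)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self._x_pad = None

    def forward(self, x, train=False):
        b, c, L = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = sliding_window_view(xp, self.kernel_size, axis=2)  # (b,c,Lp-k+1,k)
        win = win[:, :, :: self.stride]
        self._x_win = win
        self._in_len = L
        return np.einsum("bclk,ock->bol", win, self.params["w"], optimize=True)

    def backward(self, dy):
        w = self.params["w"]
        self.grads["w"] += np.einsum("bclk,bol->ock", self._x_win, dy, optimize=True)
        b = dy.shape[0]
        Lp = self._in_len + 2 * self.pad
        dxp = np.zeros((b, self.in_channels, Lp))
        Lout = dy.shape[2]
        # scatter each kernel tap back onto the padded input grid
        for j in range(self.kernel_size):
            contrib = np.einsum("bol,oc->bcl", dy, w[:, :, j], optimize=True)
            dxp[:, :, j: j + self.stride * Lout: self.stride] += contrib
        if self.pad:
            return dxp[:, :, self.pad:-self.pad]
        return dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.grads["gamma"] = np.zeros(channels)
        self.grads["beta"] = np.zeros(channels)
        self.buffers["running_mean"] = np.zeros(channels)
        self.buffers["running_var"] = np.ones(channels)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.buffers["running_mean"] *= 1 - m
            self.buffers["running_mean"] += m * mean
            self.buffers["running_var"] *= 1 - m
            self.buffers["running_var"] += m * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._xhat, self._inv, self._train = xhat, inv, train
        g = self.params["gamma"]
        return g[None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += np.einsum("bcl,bcl->c", dy, xhat)
        self.grads["beta"] += dy.sum(axis=(0, 2))
        g = self.params["gamma"][None, :, None]
        if not self._train:
            return dy * g * inv[None, :, None]
        n = dy.shape[0] * dy.shape[2]
        dxhat = dy * g
        # standard batchnorm backward through batch statistics
        return (inv[None, :, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * np.einsum("bcl,bcl->c", dxhat, xhat)[None, :, None]
        )


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool1d(Layer):
    """Non-overlapping max pooling (kernel == stride); odd tails are dropped."""

    def __init__(self, kernel_size: int = 2):
        super().__init__()
        self.k = kernel_size

    def forward(self, x, train=False):
        b, c, L = x.shape
        Lout = L // self.k
        xr = x[:, :, : Lout * self.k].reshape(b, c, Lout, self.k)
        self._arg = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        b, c, Lout = dy.shape
        dxr = np.zeros((b, c, Lout, self.k))
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, :, : Lout * self.k] = dxr.reshape(b, c, Lout * self.k)
        return dx


class GlobalAvgPool(Layer):
    """(b, c, L) -> (b, c) mean over length."""

    def forward(self, x, train=False):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._L, axis=2) / self._L


class Linear(Layer):
    """Fully connected layer; ``gain`` rescales the He init (small gains on
    output heads keep initial logits near zero)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, gain: float = 1.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = gain * _he_init(rng, (out_features, in_features), in_features)
        self.params["b"] = np.zeros(out_features)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros(out_features)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dy):
        self.grads["w"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["w"]


class Dropout(Layer):
    """Inverted dropout; active only in training mode with an attached rng."""

    def __init__(self, p: float = 0.0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0 or self.rng is None:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class _ResBase(Layer):
    """Residual add with optional projection shortcut; out = relu(f(x) + s(x))."""

    def __init__(self):
        super().__init__()
        self.body: Sequential
        self.shortcut: Sequential | None = None

    def children(self):
        return [self.body] + ([self.shortcut] if self.shortcut else [])

    def forward(self, x, train=False):
        y = self.body.forward(x, train=train)
        s = self.shortcut.forward(x, train=train) if self.shortcut else x
        self._mask = (y + s) > 0
        return np.where(self._mask, y + s, 0.0)

    def backward(self, dy):
        dy = np.where(self._mask, dy, 0.0)
        dx = self.body.backward(dy)
        if self.shortcut:
            dx = dx + self.shortcut.backward(dy)
        else:
            dx = dx + dy
        return dx


class ResidualBlock(_ResBase):
    """Basic two-convolution residual block (conv-BN-ReLU-conv-BN + skip)."""

    def __init__(self, in_channels: int, channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.body = Sequential(
            Conv1d(in_channels, channels, kernel_size, rng=rng),
            BatchNorm1d(channels), ReLU(),
            Conv1d(channels, channels, kernel_size, rng=rng),
            BatchNorm1d(channels),
        )
        if in_channels != channels:
            self.shortcut = Sequential(
                Conv1d(in_channels, channels, 1, rng=rng), BatchNorm1d(channels))


class BottleneckBlock(_ResBase):
    """ResNet50-style bottleneck: 1x1 reduce, k-conv, 1x1 expand (x4) + skip."""

    expansion = 4

    def __init__(self, in_channels: int, mid_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        out = mid_channels * self.expansion
        self.body = Sequential(
            Conv1d(in_channels, mid_channels, 1, rng=rng),
            BatchNorm1d(mid_channels), ReLU(),
            Conv1d(mid_channels, mid_channels, kernel_size, rng=rng),
            BatchNorm1d(mid_channels), ReLU(),
            Conv1d(mid_channels, out, 1, rng=rng),
            BatchNorm1d(out),
        )
        if in_channels != out:
            self.shortcut = Sequential(
                Conv1d(in_channels, out, 1, rng=rng), BatchNorm1d(out))


# ---------------------------------------------------------------------------
# state handling

def _walk(layer: Layer, prefix: str = ""):
    yield prefix, layer
    for i, child in enumerate(layer.children()):
        yield from _walk(child, f"{prefix}{i}.")


def collect_state(model: Layer, include_buffers: bool = True) -> dict[str, np.ndarray]:
    state = {}
    for prefix, lay in _walk(model):
        for k, v in lay.params.items():
            state[prefix + k] = v
        if include_buffers:
            for k, v in lay.buffers.items():
                state[prefix + "buf." + k] = v
    return state


def load_state(model: Layer, state: dict[str, np.ndarray]) -> None:
    own = collect_state(model)
    if set(own) != set(state):
        missing = set(own) ^ set(state)
        raise ValueError(f"state dict mismatch, differing keys: {sorted(missing)[:5]}")
    for k, v in state.items():
        if own[k].shape != v.shape:
            raise ValueError(f"shape mismatch for {k}: {own[k].shape} vs {v.shape}")
        own[k][...] = v


def state_hash(state: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for k in sorted(state):
        h.update(k.encode())
        h.update(np.ascontiguousarray(state[k], dtype=np.float64).tobytes())
    return h.hexdigest()[:16]


def count_parameters(model: Layer) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(v.size for prefix, lay in _walk(model) for v in lay.params.values()))


class Adam:
    """Adam with optional decoupled weight decay on weight matrices only."""

    def __init__(self, model, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        if hasattr(model, "_as_layer"):  # whole-model wrapper (e.g. Encoder)
            model = model._as_layer()
        self.model = model
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self._slots = []
        for prefix, lay in _walk(model):
            for k in lay.params:
                self._slots.append((lay, k, np.zeros_like(lay.params[k]),
                                    np.zeros_like(lay.params[k])))

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for lay, k, m, v in self._slots:
            g = lay.grads[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and k == "w":
                upd = upd + self.weight_decay * lay.params[k]
            lay.params[k] -= self.lr * upd
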