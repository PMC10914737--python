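"""Minimal numpy neural-network layers with hand-written backprop.

Covers exactly what the two networks in this package need: 1-D
convolutions (stride 1, same padding), max pooling, dense layers, an LSTM
returning the full sequence, Gaussian input noise, dropout and Adam.
Layers expose ``forward(x, train)`` / ``backward(grad)`` and hold their
parameters and gradients in dicts keyed by name.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "MaxPool1D",
    "Dense",
    "Flatten",
    "GaussianNoise",
    "Dropout",
    "SpatialDropout1D",
    "LSTM",
    "Sequential",
    "Adam",
    "softmax",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _activate(z: np.ndarray, activation: str | None) -> np.ndarray:
    if activation is None or activation == "linear":
        return z
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "sigmoid":
        return sigmoid(z)
    if activation == "softmax":
        return softmax(z)
    if activation == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {activation!r}")


def _activate_grad(grad: np.ndarray, z: np.ndarray, a: np.ndarray, activation: str | None) -> np.ndarray:
    if activation is None or activation == "linear":
        return grad
    if activation == "relu":
        return grad * (z > 0)
    if activation == "sigmoid":
        return grad * a * (1.0 - a)
    if activation == "tanh":
        return grad * (1.0 - a * a)
    raise ValueError(f"backward through {activation!r} must be fused with the loss")


class Conv1D(Layer):
    """1-D convolution, stride 1, zero 'same' padding, odd kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, activation: str | None = "relu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.kernel = kernel
        self.activation = activation
        self.params["W"] = rng.normal(0.0, scale, size=(kernel, in_ch, out_ch))
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # x: (B, T, in_ch)
        k, pad = self.kernel, self.kernel // 2
        B, T, C = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        z = np.zeros((B, T, self.params["W"].shape[2]))
        for j in range(k):
            z += xp[:, j : j + T, :] @ self.params["W"][j]
        z += self.params["b"]
        self._x, self._xp, self._z = x, xp, z
        self._a = _activate(z, self.activation)
        return self._a

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, pad = self.kernel, self.kernel // 2
        B, T, _ = self._x.shape
        dz = _activate_grad(grad, self._z, self._a, self.activation)
        W = self.params["W"]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(self._xp)
        for j in range(k):
            dW[j] = np.einsum("bti,bto->io", self._xp[:, j : j + T, :], dz)
            dxp[:, j : j + T, :] += dz @ W[j].T
        self.grads["W"] = dW
        self.grads["b"] = dz.sum(axis=(0, 1))
        return dxp[:, pad : pad + T, :] if pad else dxp


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, C = x.shape
        if T % self.pool:
            raise ValueError(f"time dimension {T} not divisible by pool {self.pool}")
        xr = x.reshape(B, T // self.pool, self.pool, C)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, T, C = self._shape
        out = np.zeros((B, T // self.pool, self.pool, C))
        b, t, c = np.ogrid[:B, : T // self.pool, :C]
        out[b, t, self._arg, c] = grad
        return out.reshape(B, T, C)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, activation: str | None = "relu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        self._z = x @ self.params["W"] + self.params["b"]
        self._a = _activate(self._z, self.activation)
        return self._a

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # softmax heads fuse their derivative into the loss gradient
        dz = grad if self.activation == "softmax" else _activate_grad(
            grad, self._z, self._a, self.activation
        )
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


class GaussianNoise(Layer):
    """Additive zero-mean Gaussian noise, active only during training."""

    def __init__(self, std: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.std = std
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train and self.std > 0:
            return x + self.rng.normal(0.0, self.std, size=x.shape)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train and self.rate > 0:
            self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class SpatialDropout1D(Dropout):
    """Drops whole feature channels of a (B, T, C) tensor."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train and self.rate > 0:
            mask = (self.rng.random((x.shape[0], 1, x.shape[2])) >= self.rate) / (1.0 - self.rate)
            self._mask = np.broadcast_to(mask, x.shape)
            return x * self._mask
        self._mask = None
        return x


class LSTM(Layer):
    """Single LSTM layer returning the full hidden-state sequence."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.units = units
        s = np.sqrt(1.0 / max(n_in, 1))
        self.params["Wx"] = rng.normal(0.0, s, size=(n_in, 4 * units))
        self.params["Wh"] = rng.normal(0.0, np.sqrt(1.0 / units), size=(units, 4 * units))
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget-gate bias
        self.params["b"] = b

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        U = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        self._cache = []
        self._x = x
        H = np.empty((B, T, U))
        xW = x @ Wx  # precompute input contributions
        for t in range(T):
            z = xW[:, t, :] + h @ Wh + b
            i = sigmoid(z[:, :U])
            f = sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = sigmoid(z[:, 3 * U :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            H[:, t, :] = h
            self._cache.append((i, f, g, o, c_prev, tc, h))
        self._H = H
        return H

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, I = x.shape
        U = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * U)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h = self._cache[t]
            dh = grad[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            h_prev = self._cache[t - 1][6] if t > 0 else np.zeros((B, U))
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.parameters())
            else:
                out.extend((layer, name) for name in layer.params)
        return out


class Adam:
    """Adaptive-moment optimizer over (layer, param-name) handles."""

    def __init__(self, handles: list[tuple[Layer, str]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 l1: float = 0.0, l2: float = 0.0):
        self.handles = handles
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.l1, self.l2 = l1, l2
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in handles]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in handles]

    def step(self) -> None:
        self.t += 1
        for k, (layer, name) in enumerate(self.handles):
            g = layer.grads.get(name)
            if g is None:
                continue
            p = layer.params[name]
            if name != "b":  # regularize weights only
                if self.l2:
                    g = g + 2.0 * self.l2 * p
                if self.l1:
                    g = g + self.l1 * np.sign(p)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            layer.params[name] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
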