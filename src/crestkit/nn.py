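"""Minimal feed-forward network core with exact backpropagation.

Implements the handful of layer types the sequence models need — 1-D
(dilated) convolutions, batch normalization, dense layers, global pooling,
dropout — together with an Adam optimizer. Every layer propagates gradients
to its input, so the same backward pass that trains the model also yields
d(score)/d(input) for nucleotide-level attribution.

Shapes: sequence tensors are [batch, length, channels]; dense tensors are
[batch, features]. All math is float64 numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "BatchNorm",
    "Activation",
    "Dense",
    "GlobalAvgPool",
    "Dropout",
    "Residual",
    "Network",
    "Adam",
]


def _act(name: str):
    if name == "relu":
        return (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(z.dtype))
    if name == "gelu":
        # tanh approximation; derivative computed consistently with it
        c = np.sqrt(2.0 / np.pi)

        def f(z):
            return 0.5 * z * (1.0 + np.tanh(c * (z + 0.044715 * z**3)))

        def df(z):
            t = np.tanh(c * (z + 0.044715 * z**3))
            dt = (1 - t**2) * c * (1 + 3 * 0.044715 * z**2)
            return 0.5 * (1 + t) + 0.5 * z * dt

        return f, df
    if name == "swish":
        def f(z):
            return z / (1.0 + np.exp(-z))

        def df(z):
            s = 1.0 / (1.0 + np.exp(-z))
            return s * (1 + z * (1 - s))

        return f, df
    if name == "softplus":
        def f(z):
            return np.logaddexp(0.0, z)

        def df(z):
            return 1.0 / (1.0 + np.exp(-z))

        return f, df
    if name == "sigmoid":
        def f(z):
            return 1.0 / (1.0 + np.exp(-z))

        def df(z):
            s = 1.0 / (1.0 + np.exp(-z))
            return s * (1 - s)

        return f, df
    if name == "identity":
        return (lambda z: z, lambda z: np.ones_like(z))
    raise ValueError(f"unknown activation {name!r}")


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution with optional dilation."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1, rng=None):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("odd kernel sizes only (same padding)")
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (kernel * c_in))  # He init
        self.params = {
            "W": rng.normal(0.0, scale, size=(kernel, c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.kernel, self.dilation = kernel, dilation
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, train):
        B, L, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        pad = (self.kernel - 1) * self.dilation // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        idx = np.arange(L)[:, None] + np.arange(self.kernel)[None, :] * self.dilation
        patches = xp[:, idx, :]  # [B, L, K, Cin]
        self._cache = (patches, x.shape, pad)
        out = np.einsum("blkc,kco->blo", patches, self.params["W"], optimize=True)
        return out + self.params["b"]

    def backward(self, dout):
        patches, (B, L, C), pad = self._cache
        self.grads["W"] = np.einsum("blkc,blo->kco", patches, dout, optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 1))
        dxp = np.zeros((B, L + 2 * pad, C))
        W = self.params["W"]
        for k in range(self.kernel):
            off = k * self.dilation
            dxp[:, off : off + L, :] += dout @ W[k].T
        return dxp[:, pad : pad + L, :]


class BatchNorm(Layer):
    """Batch normalization over (batch, length) per channel."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, train, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv, axes, train, shape = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"]
        if not train:
            return dout * g * inv
        n = np.prod([shape[a] for a in axes])
        dxhat = dout * g
        return inv / n * (n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))


class Activation(Layer):
    def __init__(self, name: str):
        super().__init__()
        self.name = name
        self.f, self.df = _act(name)

    def forward(self, x, train):
        self._z = x
        return self.f(x)

    def backward(self, dout):
        return dout * self.df(self._z)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0.0, scale, size=(n_in, n_out)), "b": np.zeros(n_out)}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._L, axis=1) / self._L


class Dropout(Layer):
    """Inverted dropout; identity in inference mode. Needs an rng attached."""

    def __init__(self, p: float):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Residual(Layer):
    """y = x + f(x) for a sub-stack f with matching shapes."""

    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, train):
        h = x
        for layer in self.layers:
            h = layer.forward(h, train)
        return x + h

    def backward(self, dout):
        dh = dout
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dout + dh


def _walk(layers):
    for layer in layers:
        if isinstance(layer, Residual):
            yield from _walk(layer.layers)
        else:
            yield layer


class Network:
    """A sequential stack with forward, backward and weight (de)serialization."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, train)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = dout
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dh

    def flat_layers(self) -> list[Layer]:
        return list(_walk(self.layers))

    def seed_dropout(self, seed: int) -> None:
        for i, layer in enumerate(self.flat_layers()):
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(seed + 1000 * (i + 1))

    def n_params(self) -> int:
        return sum(p.size for layer in self.flat_layers() for p in layer.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.flat_layers()):
            for name, arr in layer.params.items():
                state[f"{i}.{name}"] = arr.copy()
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.flat_layers()):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()


class Adam:
    def __init__(self, network: Network, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, layer in enumerate(self.network.flat_layers()):
            for name, param in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (i, name)
                m = self.m.setdefault(key, np.zeros_like(param))
                v = self.v.setdefault(key, np.zeros_like(param))
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                param -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
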