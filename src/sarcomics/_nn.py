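"""Minimal CPU neural-network layers for the convolutional autoencoder.

Implements exactly what the CAE/HSCAE needs: strided convolution via
im2col, nearest-neighbor upsampling, dense layers, ReLU/sigmoid, and
Adam. All arrays are float64 and every source of randomness is an
explicit ``numpy.random.Generator``, so training is bit-reproducible.
Layout convention is (N, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "Dense", "ReLU", "Sigmoid", "Flatten", "Reshape",
           "Upsample2x", "Sequential", "Adam"]


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation), square kernel, zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, kernel, stride, pad
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(fan_in, c_out))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]        # N,C,Ho,Wo,k,k
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, -1)
        self._cache = (cols, x.shape, xp.shape, ho, wo)
        y = cols @ self.params["W"] + self.params["b"]
        return y.transpose(0, 3, 1, 2)

    def backward(self, gy):
        cols, x_shape, xp_shape, ho, wo = self._cache
        n = x_shape[0]
        g = gy.transpose(0, 2, 3, 1)                         # N,Ho,Wo,Cout
        self.grads["W"] = cols.reshape(-1, cols.shape[-1]).T @ g.reshape(-1, self.c_out)
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        gcols = (g @ self.params["W"].T).reshape(n, ho, wo, self.c_in, self.k, self.k)
        gxp = np.zeros(xp_shape)
        s = self.stride
        for ki in range(self.k):
            for kj in range(self.k):
                gxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += \
                    gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        p = self.pad
        if p:
            return gxp[:, :, p:-p, p:-p]
        return gxp


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        self.grads["W"] = self._x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, gy):
        return gy.reshape(gy.shape[0], -1)


class Upsample2x(Layer):
    """Nearest-neighbor doubling of the spatial grid."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def backward_from(self, gy, stop_after: int):
        """Backpropagate down to (and excluding) layer index ``stop_after``;
        returns the gradient w.r.t. that layer's output."""
        for layer in reversed(self.layers[stop_after + 1:]):
            gy = layer.backward(gy)
        return gy

    def parameters(self):
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append((layer, name))
        return out


class Adam:
    def __init__(self, modules, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.entries = []
        for mod in modules:
            if isinstance(mod, Sequential):
                self.entries.extend(mod.parameters())
            else:
                self.entries.extend((mod, name) for name in mod.params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.entries]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.entries]

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.entries):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            layer.params[name] -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for layer, name in self.entries:
            layer.grads[name] = None
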