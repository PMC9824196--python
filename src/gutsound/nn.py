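"""Minimal neural-network layers with explicit backprop, in numpy.

The classifier inputs here are tiny (3x11 patches), so a hand-written
forward/backward pass with an Adam optimizer is fast, dependency-free and
bit-reproducible. Layers follow the usual contract: ``forward(x, train)``
caches what ``backward(dy)`` needs; parameters and their gradients live in
per-layer dicts keyed by name.

Weight initialization is seeded uniform fan-in: U(-1/sqrt(fan_in), +1/sqrt(fan_in)).
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Base layer: stateless unless it declares params/grads."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2d(Layer):
    """Same-padded 2-D convolution via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: Tuple[int, int], rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kh, self.kw = kernel
        if self.kh % 2 != 1 or self.kw % 2 != 1:
            raise ConfigError("conv kernel sides must be odd for same padding")
        fan_in = in_ch * self.kh * self.kw
        self.params = {
            "W": _uniform_fan_in(rng, fan_in, (out_ch, fan_in)),
            "b": _uniform_fan_in(rng, fan_in, (out_ch,)),
        }

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * self.kh * self.kw)
        self._cache = (cols, x.shape)
        y = cols @ self.params["W"].T + self.params["b"]
        return y.transpose(0, 2, 1).reshape(n, self.out_ch, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, c, h, w = x_shape
        dyf = dy.reshape(n, self.out_ch, h * w).transpose(0, 2, 1)  # [n, hw, out]
        self.grads["W"] = np.tensordot(dyf, cols, axes=([0, 1], [0, 1]))
        self.grads["b"] = dyf.sum(axis=(0, 1))
        dcols = (dyf @ self.params["W"]).reshape(n, h, w, c, self.kh, self.kw)
        ph, pw = self.kh // 2, self.kw // 2
        dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, ph : ph + h, pw : pw + w]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(n_ch), "beta": np.zeros(n_ch)}
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        self._cache = (xhat, inv_std, x.shape, train)
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, x_shape, was_train = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][:, None, None]
        dxhat = dy * g
        if not was_train:
            # eval mode normalizes with fixed running statistics
            return dxhat * inv_std[:, None, None]
        # standard batch-norm backward, reduced over batch and spatial axes
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv_std[:, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPoolTime(Layer):
    """Max-pool over the time (width) axis only, window/stride 2.

    Odd trailing columns are dropped (floor division), so width follows
    11 -> 5 -> 2 -> 1 across three pools; the 3-row frequency axis survives.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        w2 = w // 2
        if w2 < 1:
            raise ConfigError(f"cannot pool time axis of width {w} below 1")
        xs = x[..., : 2 * w2].reshape(n, c, h, w2, 2)
        self._idx = xs.argmax(axis=-1)
        self._in_shape = x.shape
        return xs.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        w2 = w // 2
        dx = np.zeros((n, c, h, w2, 2))
        np.put_along_axis(dx, self._idx[..., None], dy[..., None], axis=-1)
        out = np.zeros((n, c, h, w))
        out[..., : 2 * w2] = dx.reshape(n, c, h, 2 * w2)
        return out


class Dropout(Layer):
    """Inverted dropout; identity at eval time. Uses a dedicated generator
    so training batches and dropout masks draw from separate streams."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ConfigError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": _uniform_fan_in(rng, in_dim, (in_dim, out_dim)),
            "b": _uniform_fan_in(rng, in_dim, (out_dim,)),
        }

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class LSTM(Layer):
    """Stacked LSTM over a [batch, time, features] sequence.

    Gate layout in the combined weight matrix is (input, forget, cell,
    output); forget-gate biases start at +1. ``forward`` returns the final
    hidden state of the top layer.
    """

    def __init__(self, input_dim: int, hidden: int, n_layers: int, rng: np.random.Generator):
        super().__init__()
        self.hidden, self.n_layers = hidden, n_layers
        for l in range(n_layers):
            d_in = input_dim if l == 0 else hidden
            self.params[f"W{l}"] = _uniform_fan_in(rng, d_in + hidden, (d_in + hidden, 4 * hidden))
            b = np.zeros(4 * hidden)
            b[hidden : 2 * hidden] = 1.0
            self.params[f"b{l}"] = b

    @staticmethod
    def _sigmoid(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-z))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, t_len, _ = x.shape
        hdim = self.hidden
        self._caches: List[List[tuple]] = []
        seq = x
        for l in range(self.n_layers):
            w, b = self.params[f"W{l}"], self.params[f"b{l}"]
            h = np.zeros((n, hdim))
            c = np.zeros((n, hdim))
            layer_cache, outputs = [], []
            for t in range(t_len):
                xt = seq[:, t, :]
                zin = np.concatenate([xt, h], axis=1)
                z = zin @ w + b
                i = self._sigmoid(z[:, :hdim])
                f = self._sigmoid(z[:, hdim : 2 * hdim])
                g = np.tanh(z[:, 2 * hdim : 3 * hdim])
                o = self._sigmoid(z[:, 3 * hdim :])
                c_next = f * c + i * g
                tanh_c = np.tanh(c_next)
                h_next = o * tanh_c
                layer_cache.append((zin, i, f, g, o, c, tanh_c))
                outputs.append(h_next)
                h, c = h_next, c_next
            self._caches.append(layer_cache)
            seq = np.stack(outputs, axis=1)
        self._top_seq_shape = seq.shape
        return seq[:, -1, :]

    def backward(self, dh_final: np.ndarray) -> np.ndarray:
        n, t_len, _ = self._top_seq_shape
        hdim = self.hidden
        # gradient w.r.t. each layer's output sequence; top layer only sees
        # the final-state gradient
        dseq = np.zeros((n, t_len, hdim))
        dseq[:, -1, :] = dh_final
        dx_seq = None
        for l in reversed(range(self.n_layers)):
            w = self.params[f"W{l}"]
            dW = np.zeros_like(w)
            db = np.zeros_like(self.params[f"b{l}"])
            d_in = w.shape[0] - hdim
            dx_seq = np.zeros((n, t_len, d_in))
            dh = np.zeros((n, hdim))
            dc = np.zeros((n, hdim))
            for t in reversed(range(t_len)):
                zin, i, f, g, o, c_prev, tanh_c = self._caches[l][t]
                dh = dh + dseq[:, t, :]
                do = dh * tanh_c
                dc = dc + dh * o * (1.0 - tanh_c**2)
                di, df, dg = dc * g, dc * c_prev, dc * i
                dz = np.concatenate(
                    [
                        di * i * (1 - i),
                        df * f * (1 - f),
                        dg * (1 - g**2),
                        do * o * (1 - o),
                    ],
                    axis=1,
                )
                dW += zin.T @ dz
                db += dz.sum(axis=0)
                dzin = dz @ w.T
                dx_seq[:, t, :] = dzin[:, :d_in]
                dh = dzin[:, d_in:]
                dc = dc * f
            self.grads[f"W{l}"] = dW
            self.grads[f"b{l}"] = db
            dseq = dx_seq
        return dx_seq


class Sequential:
    """A feed-forward chain of layers."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> List[Tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: Optional[np.ndarray] = None
) -> Tuple[float, np.ndarray]:
    """Mean two-class cross-entropy and its gradient w.r.t. the logits."""
    n = len(y)
    p = softmax(logits)
    w = np.ones(n) if class_weights is None else class_weights[y]
    eps = 1e-12
    loss = float(-(w * np.log(p[np.arange(n), y] + eps)).sum() / w.sum())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / w.sum())[:, None]
    return loss, dlogits


class Adam:
    """Adam with bias correction over a Sequential's parameters."""

    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr, self.beta1, self.beta2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()} for l in net.layers}
        self.v = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()} for l in net.layers}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer in self.net.layers:
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                m = self.m[id(layer)][name]
                v = self.v[id(layer)][name]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
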