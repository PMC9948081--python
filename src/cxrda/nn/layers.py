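"""Minimal feed-forward layer library with manual backpropagation.

All image tensors are NHWC ``float`` arrays.  Every layer caches what its
backward pass needs during ``forward`` and accumulates parameter gradients
into ``self.grads`` during ``backward`` (callers zero them between steps).
The library covers exactly what the adaptation networks need: dense layers,
strided (transposed) convolutions, batch normalization, pooling, dropout and
the usual activations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Sequential",
    "Dense",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm",
    "ReLU",
    "Sigmoid",
    "Softmax",
    "Dropout",
    "MaxPool2",
    "GlobalAvgPool",
    "Flatten",
    "Reshape",
    "conv_output_side",
    "conv_transpose_output_side",
]


def conv_output_side(side: int, kernel: int, stride: int, padding: str) -> int:
    """Spatial side produced by a convolution."""
    if padding == "same":
        return -(-side // stride)
    if padding == "valid":
        return (side - kernel) // stride + 1
    raise ValueError(f"unknown padding {padding!r}")


def conv_transpose_output_side(side: int, kernel: int, stride: int, padding: str) -> int:
    """Spatial side produced by a transposed convolution.

    ``valid``: out = (in - 1) * stride + kernel;  ``same``: out = in * stride.
    """
    if padding == "valid":
        return (side - 1) * stride + kernel
    if padding == "same":
        return side * stride
    raise ValueError(f"unknown padding {padding!r}")


class Layer:
    """Base class: parameter dict, gradient dict, training flag."""

    trainable = True

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for layer in self.layers:
            layer.training = flag
            if isinstance(layer, Sequential):
                layer.set_training(flag)

    def freeze_bn_stats(self, flag: bool) -> None:
        for layer in self.iter_layers():
            if isinstance(layer, BatchNorm):
                layer.frozen_stats = flag

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer

    def trainable_params(self):
        """Deterministically ordered (layer, name) pairs of trainable parameters."""
        out = []
        for layer in self.iter_layers():
            if not layer.trainable:
                continue
            for name in sorted(layer.params):
                out.append((layer, name))
        return out

    def n_params(self, trainable_only: bool = False) -> int:
        layers = self.iter_layers()
        return int(
            sum(
                p.size
                for layer in layers
                if not (trainable_only and not layer.trainable)
                for p in layer.params.values()
            )
        )

    def param_ids(self, trainable_only: bool = True):
        return {id(layer.params[name]) for layer, name in self.trainable_params()} if trainable_only else {
            id(p) for layer in self.iter_layers() for p in layer.params.values()
        }


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params["W"] = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)
        self.zero_grads()

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] += self._x.T @ g
        self.grads["b"] += g.sum(axis=0)
        return g @ self.params["W"].T


def _pad_amounts(side: int, kernel: int, stride: int, padding: str) -> tuple[int, int]:
    if padding == "valid":
        return 0, 0
    out = conv_output_side(side, kernel, stride, padding)
    total = max((out - 1) * stride + kernel - side, 0)
    return total // 2, total - total // 2


class Conv2D(Layer):
    """2-D convolution, NHWC, weights of shape (k, k, c_in, c_out)."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, padding="same",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.params["W"] = (rng.standard_normal((kernel, kernel, c_in, c_out)) * scale).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.zero_grads()

    def forward(self, x):
        k, s = self.kernel, self.stride
        n, h, w, _ = x.shape
        ph = _pad_amounts(h, k, s, self.padding)
        pw = _pad_amounts(w, k, s, self.padding)
        xp = np.pad(x, ((0, 0), ph, pw, (0, 0))) if (ph != (0, 0) or pw != (0, 0)) else x
        ho = conv_output_side(h, k, s, self.padding)
        wo = conv_output_side(w, k, s, self.padding)
        W = self.params["W"]
        y = np.tile(self.params["b"], (n, ho, wo, 1)).astype(W.dtype)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di : di + (ho - 1) * s + 1 : s, dj : dj + (wo - 1) * s + 1 : s, :]
                y += xs @ W[di, dj]
        self._xp, self._pads, self._in_shape, self._out_hw = xp, (ph, pw), x.shape, (ho, wo)
        return y

    def backward(self, g):
        k, s = self.kernel, self.stride
        xp = self._xp
        (ph, pw) = self._pads
        ho, wo = self._out_hw
        W = self.params["W"]
        dxp = np.zeros_like(xp)
        gm = g.reshape(-1, g.shape[-1])
        for di in range(k):
            for dj in range(k):
                sl = np.s_[:, di : di + (ho - 1) * s + 1 : s, dj : dj + (wo - 1) * s + 1 : s, :]
                xs = xp[sl]
                self.grads["W"][di, dj] += xs.reshape(-1, xs.shape[-1]).T @ gm
                dxp[sl] += g @ W[di, dj].T
        self.grads["b"] += g.sum(axis=(0, 1, 2))
        _, h, w, _ = self._in_shape
        return dxp[:, ph[0] : ph[0] + h, pw[0] : pw[0] + w, :]


class ConvTranspose2D(Layer):
    """Transposed 2-D convolution (adjoint of Conv2D's forward map).

    ``valid`` produces (in-1)*stride + kernel; ``same`` produces in*stride by
    symmetrically cropping the full output (kernel >= stride required).
    """

    def __init__(self, c_in, c_out, kernel=3, stride=1, padding="valid",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if padding == "same" and kernel < stride:
            raise ValueError("'same' transposed convolution requires kernel >= stride")
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.params["W"] = (rng.standard_normal((kernel, kernel, c_in, c_out)) * scale).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.zero_grads()

    def _crop(self, full: int, out: int) -> int:
        total = full - out
        return total // 2

    def forward(self, x):
        k, s = self.kernel, self.stride
        n, h, w, _ = x.shape
        hf = (h - 1) * s + k
        wf = (w - 1) * s + k
        W = self.params["W"]
        yf = np.zeros((n, hf, wf, W.shape[-1]), dtype=W.dtype)
        for di in range(k):
            for dj in range(k):
                yf[:, di : di + (h - 1) * s + 1 : s, dj : dj + (w - 1) * s + 1 : s, :] += x @ W[di, dj]
        ho = conv_transpose_output_side(h, k, s, self.padding)
        wo = conv_transpose_output_side(w, k, s, self.padding)
        cb_h, cb_w = self._crop(hf, ho), self._crop(wf, wo)
        y = yf[:, cb_h : cb_h + ho, cb_w : cb_w + wo, :] + self.params["b"]
        self._x, self._full, self._crops, self._out_hw = x, (hf, wf), (cb_h, cb_w), (ho, wo)
        return y

    def backward(self, g):
        k, s = self.kernel, self.stride
        x = self._x
        n, h, w, _ = x.shape
        hf, wf = self._full
        cb_h, cb_w = self._crops
        ho, wo = self._out_hw
        W = self.params["W"]
        gf = np.zeros((n, hf, wf, g.shape[-1]), dtype=g.dtype)
        gf[:, cb_h : cb_h + ho, cb_w : cb_w + wo, :] = g
        dx = np.zeros_like(x)
        xm = x.reshape(-1, x.shape[-1])
        for di in range(k):
            for dj in range(k):
                gs = gf[:, di : di + (h - 1) * s + 1 : s, dj : dj + (w - 1) * s + 1 : s, :]
                self.grads["W"][di, dj] += xm.T @ gs.reshape(-1, gs.shape[-1])
                dx += gs @ W[di, dj].T
        self.grads["b"] += g.sum(axis=(0, 1, 2))
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channels)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self.frozen_stats = False
        self.zero_grads()

    def forward(self, x):
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if not self.frozen_stats:
                m = self.momentum
                self.running_mean = m * self.running_mean + (1 - m) * mean
                self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat, self._inv, self._axes = xhat, inv, axes
        self._m = x.size // x.shape[-1]
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, g):
        xhat, inv, axes, m = self._xhat, self._inv, self._axes, self._m
        self.grads["gamma"] += (g * xhat).sum(axis=axes)
        self.grads["beta"] += g.sum(axis=axes)
        gx = g * self.params["gamma"]
        if not self.training:
            return gx * inv
        t1 = gx.sum(axis=axes)
        t2 = (gx * xhat).sum(axis=axes)
        return (inv / m) * (m * gx - t1 - xhat * t2)


class ReLU(Layer):
    trainable = False

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Sigmoid(Layer):
    trainable = False

    def forward(self, x):
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, g):
        y = self._y
        return g * y * (1.0 - y)


class Softmax(Layer):
    trainable = False

    def forward(self, x):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, g):
        y = self._y
        return y * (g - (g * y).sum(axis=-1, keepdims=True))


class Dropout(Layer):
    """Inverted dropout; active only in training mode. Draws from ``rng``."""

    trainable = False

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; spatial sides must be even."""

    trainable = False

    def forward(self, x):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial sides")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, h // 2, w // 2, 4, c)
        self._idx = xr.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, g):
        n, h, w, c = self._in_shape
        gr = np.zeros((n, h // 2, w // 2, 4, c), dtype=g.dtype)
        np.put_along_axis(gr, self._idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gr = gr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return gr.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    trainable = False

    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        n, h, w, c = self._in_shape
        return np.broadcast_to(g[:, None, None, :] / (h * w), self._in_shape).copy()


class Flatten(Layer):
    trainable = False

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._in_shape)


class Reshape(Layer):
    trainable = False

    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, g):
        return g.reshape(self._in_shape)
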