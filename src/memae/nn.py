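"""Minimal NumPy layers for 1-D convolutional autoencoders.

Implements exactly what the encoder/decoder stacks need: strided 1-D
convolution (via im2col), fractionally-strided (transposed) convolution as
its adjoint, batch normalization with running statistics, ReLU, and Adam.
Every layer caches its forward intermediates and implements an explicit
backward pass; correctness is pinned by finite-difference tests.

Arrays are ``(batch, channels, time)`` throughout, float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "ConvTranspose1d", "BatchNorm1d", "ReLU", "Sequential", "Adam"]


def _im2col(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """(B, C, Tp) padded input -> (B, L, C*kernel) window matrix."""
    b, c, tp = xp.shape
    length = (tp - kernel) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)
    cols = windows[:, :, ::stride][:, :, :length]  # (B, C, L, K)
    return np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(b, length, c * kernel)


def _col2im(cols: np.ndarray, shape: tuple, kernel: int, stride: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add windows back to (B, C, Tp)."""
    b, c, tp = shape
    length = cols.shape[1]
    colsr = cols.reshape(b, length, c, kernel).transpose(0, 2, 1, 3)  # (B, C, L, K)
    xp = np.zeros(shape, dtype=cols.dtype)
    for k in range(kernel):
        xp[:, :, k : k + stride * length : stride] += colsr[:, :, :, k]
    return xp


class Layer:
    """Base: parameterless layers leave ``params``/``grads`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.cin, self.cout = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = np.random.default_rng() if rng is None else rng
        bound = 1.0 / np.sqrt(in_channels * kernel)
        self.params = {
            "weight": rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel)),
            "bias": rng.uniform(-bound, bound, size=out_channels),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        if xp.shape[2] < self.kernel:
            raise ValueError("input shorter than kernel after padding")
        cols = _im2col(xp, self.kernel, self.stride)
        b, length, width = cols.shape
        wmat = self.params["weight"].reshape(self.cout, -1)
        y = (cols.reshape(b * length, width) @ wmat.T + self.params["bias"])
        self._cache = (cols, xp.shape, x.shape[2])
        return y.reshape(b, length, self.cout).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, t_in = self._cache
        b, length, width = cols.shape
        dymat = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(b * length, self.cout)
        colsmat = cols.reshape(b * length, width)
        wmat = self.params["weight"].reshape(self.cout, -1)
        self.grads["weight"][...] = (dymat.T @ colsmat).reshape(
            self.params["weight"].shape)
        self.grads["bias"][...] = dy.sum(axis=(0, 2))
        dcols = (dymat @ wmat).reshape(b, length, width)
        dxp = _col2im(dcols, xp_shape, self.kernel, self.stride)
        p = self.padding
        return dxp[:, :, p : p + t_in] if p else dxp


class ConvTranspose1d(Layer):
    """Fractionally-strided convolution: the exact adjoint of :class:`Conv1d`."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, output_padding: int = 0,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if output_padding >= stride:
            raise ValueError("output_padding must be < stride")
        self.cin, self.cout = in_channels, out_channels
        self.kernel, self.stride = kernel, stride
        self.padding, self.output_padding = padding, output_padding
        rng = np.random.default_rng() if rng is None else rng
        bound = 1.0 / np.sqrt(in_channels * kernel)
        self.params = {
            "weight": rng.uniform(-bound, bound, size=(in_channels, out_channels, kernel)),
            "bias": rng.uniform(-bound, bound, size=out_channels),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def out_length(self, t_in: int) -> int:
        return (t_in - 1) * self.stride - 2 * self.padding + self.kernel + self.output_padding

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        b, _, t_in = x.shape
        wmat = self.params["weight"].reshape(self.cin, -1)  # (C_in, C_out*K)
        xt = np.ascontiguousarray(x.transpose(0, 2, 1)).reshape(b * t_in, self.cin)
        cols = (xt @ wmat).reshape(b, t_in, -1)  # (B, T_in, C_out*K)
        tp = (t_in - 1) * self.stride + self.kernel + self.output_padding
        yp = _col2im(cols, (b, self.cout, tp), self.kernel, self.stride)
        p = self.padding
        y = yp[:, :, p : p + self.out_length(t_in)]
        self._cache = (x, tp)
        return y + self.params["bias"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, tp = self._cache
        b, _, t_in = x.shape
        p = self.padding
        dyp = np.zeros((b, self.cout, tp), dtype=dy.dtype)
        dyp[:, :, p : p + dy.shape[2]] = dy
        dcols = _im2col(dyp, self.kernel, self.stride)  # (B, T_in, C_out*K)
        wmat = self.params["weight"].reshape(self.cin, -1)
        xt = np.ascontiguousarray(x.transpose(0, 2, 1)).reshape(b * t_in, self.cin)
        dcolsmat = dcols.reshape(b * t_in, -1)
        self.grads["weight"][...] = (xt.T @ dcolsmat).reshape(
            self.params["weight"].shape)
        self.grads["bias"][...] = dy.sum(axis=(0, 2))
        return (dcolsmat @ wmat.T).reshape(b, t_in, self.cin).transpose(0, 2, 1)


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, time); running stats at eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, training)
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, training = self._cache
        self.grads["gamma"][...] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"][...] = dy.sum(axis=(0, 2))
        g = self.params["gamma"][None, :, None]
        if not training:
            return dy * g * inv[None, :, None]
        n = dy.shape[0] * dy.shape[2]
        dxhat = dy * g
        return (inv[None, :, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def param_items(self):
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield (i, name), value, layer.grads[name]


class Adam:
    """Adaptive-moment gradient descent over arbitrary (key, param, grad) triples."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, triples) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, param, grad in triples:
            m = self._m.setdefault(key, np.zeros_like(param))
            v = self._v.setdefault(key, np.zeros_like(param))
            m += (1 - b1) * (grad - m)
            v += (1 - b2) * (grad * grad - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
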