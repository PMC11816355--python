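"""Neural-network layers with explicit backward passes (channels-last)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
]

F32 = np.float32


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # Serialization: state includes parameters plus any buffers (BN stats).
    def state(self) -> list[np.ndarray]:
        return list(self.params)

    def load_state(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.params, arrays, strict=True):
            p[...] = a


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    out = -(-length // stride)  # ceil
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return out, left, total - left


def _im2col(xp: np.ndarray, kernel: int, stride: int, out_len: int) -> np.ndarray:
    """View a padded (B, Lp, C) array as (B, out_len, kernel, C) windows."""
    sb, sl, sc = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(xp.shape[0], out_len, kernel, xp.shape[2]),
        strides=(sb, stride * sl, sl, sc),
        writeable=False,
    )


class Conv1d(Layer):
    """Same-padded 1D convolution, channels-last, no bias (BN follows)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        std = np.sqrt(2.0 / (kernel * c_in))
        self.w = rng.normal(0.0, std, size=(kernel * c_in, c_out)).astype(F32)
        self.params = [self.w]
        self.grads = [np.zeros_like(self.w)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        out, pl, pr = _same_pad(L, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        col = _im2col(xp, self.kernel, self.stride, out)
        col = np.ascontiguousarray(col).reshape(B * out, self.kernel * C)
        y = col @ self.w
        if training:
            self._cache = (col, B, L, out, pl, pr)
        return y.reshape(B, out, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, B, L, out, pl, pr = self._cache
        dyf = dy.reshape(B * out, self.c_out)
        self.grads[0][...] = col.T @ dyf
        dcol = (dyf @ self.w.T).reshape(B, out, self.kernel, self.c_in)
        dxp = np.zeros((B, L + pl + pr, self.c_in), dtype=F32)
        for j in range(self.kernel):
            dxp[:, j : j + self.stride * out : self.stride, :] += dcol[:, :, j, :]
        self._cache = None
        return dxp[:, pl : pl + L, :]


class BatchNorm1d(Layer):
    """Batch normalization over (batch, length) per channel."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            n = x.shape[0] * x.shape[1]
            mean = np.einsum("blc->c", x) / n
            var = np.einsum("blc,blc->c", x, x) / n - mean * mean
            np.maximum(var, 0.0, out=var)
            self.running_mean[...] = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var[...] = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean.astype(F32)) * invstd
        if training:
            self._cache = (xhat, invstd, x.shape[0] * x.shape[1])
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, n = self._cache
        g_gamma = np.einsum("blc,blc->c", dy, xhat)
        g_beta = np.einsum("blc->c", dy)
        self.grads[0][...] = g_gamma
        self.grads[1][...] = g_beta
        dx = (self.gamma * invstd) * (
            dy - (g_beta / n) - xhat * (g_gamma / n)
        )
        self._cache = None
        return dx.astype(F32, copy=False)

    def state(self) -> list[np.ndarray]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        for buf, a in zip(self.state(), arrays, strict=True):
            buf[...] = a


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool1d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2) -> None:
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        out, pl, pr = _same_pad(L, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)), constant_values=-np.inf)
        col = _im2col(xp, self.kernel, self.stride, out)
        idx = np.argmax(col, axis=2)
        y = np.take_along_axis(col, idx[:, :, None, :], axis=2)[:, :, 0, :]
        if training:
            self._cache = (idx, B, L, out, pl, pr)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, B, L, out, pl, pr = self._cache
        dxp = np.zeros((B, L + pl + pr, dy.shape[2]), dtype=F32)
        for j in range(self.kernel):
            sel = idx == j
            target = dxp[:, j : j + self.stride * out : self.stride, :]
            target += np.where(sel, dy, 0.0)
        self._cache = None
        return dxp[:, pl : pl + L, :]


class Flatten(Layer):
    """(B, L, C) -> (B, L*C); preserves positional information."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.broadcast_to(
            (dy / self._len)[:, None, :], (dy.shape[0], self._len, dy.shape[1])
        )


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 w_scale: float = 1.0) -> None:
        super().__init__()
        std = w_scale * np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, std, size=(n_in, n_out)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def walk(self) -> list[Layer]:
        out = []
        for layer in self.layers:
            out.extend(layer.walk() if hasattr(layer, "walk") else [layer])
        return out


class Adam:
    """Adam over the parameters of a list of layer trees."""

    def __init__(self, modules: list[Layer], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.leaves: list[Layer] = []
        for m in modules:
            self.leaves.extend(m.walk() if hasattr(m, "walk") else [m])
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in lf.params] for lf in self.leaves]
        self.v = [[np.zeros_like(p) for p in lf.params] for lf in self.leaves]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for lf, ms, vs in zip(self.leaves, self.m, self.v):
            for p, g, m, v in zip(lf.params, lf.grads, ms, vs):
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
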