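"""Minimal 1-D neural-network layers with explicit forward/backward passes.

The denoising network needs only a handful of primitives: same-padded 1-D
convolution, ReLU, factor-2 max pooling, factor-2 transposed convolution,
fully connected layers, and the sigmoid-gated channel / spatial attention
blocks.  They are implemented directly on NumPy arrays in (batch, channels,
length) layout with analytically derived gradients; convolutions are lowered
to matrix multiplications (im2col) so the heavy lifting runs in BLAS.
Activations are kept in float32.

Gradient correctness is verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv1d", "ReLU", "MaxPool2", "UpConv2", "Linear",
    "ChannelAttention", "SpatialAttention", "ConvBlock", "he_init",
]

DTYPE = np.float32


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: tracks parameter arrays and their gradients in lock-step."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def _register(self, *arrays: np.ndarray) -> list[np.ndarray]:
        self.params.extend(arrays)
        grads = [np.zeros_like(a) for a in arrays]
        self.grads.extend(grads)
        return list(arrays)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def sublayers(self) -> list["Layer"]:
        return []

    def all_params(self) -> list[np.ndarray]:
        out = list(self.params)
        for sub in self.sublayers():
            out.extend(sub.all_params())
        return out

    def all_grads(self) -> list[np.ndarray]:
        out = list(self.grads)
        for sub in self.sublayers():
            out.extend(sub.all_grads())
        return out


class Conv1d(Layer):
    """Same-padded 1-D convolution with odd kernel size, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.w = he_init(rng, (c_out, c_in * kernel), fan_in=c_in * kernel)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self._register(self.w, self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        P = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (P, P)))
        # (B, C, L, K) sliding windows -> (B*L, C*K) for one big GEMM
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * L, C * self.kernel)
        self._cols, self._shape = cols, (B, C, L)
        y = cols @ self.w.T + self.b
        return np.ascontiguousarray(y.reshape(B, L, self.c_out).transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        K, P = self.kernel, self.kernel // 2
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * L, self.c_out)
        self.grads[0] += dyt.T @ self._cols
        self.grads[1] += dyt.sum(axis=0)
        dcols = (dyt @ self.w).reshape(B, L, C, K).transpose(0, 2, 1, 3)
        dxp = np.zeros((B, C, L + 2 * P), dtype=DTYPE)
        for k in range(K):
            dxp[:, :, k:k + L] += dcols[:, :, :, k]
        return dxp[:, :, P:P + L]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class MaxPool2(Layer):
    """Non-overlapping max pooling over pairs along the length axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        xr = x.reshape(B, C, L // 2, 2)
        self._idx = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        dxr = np.zeros((B, C, L // 2, 2), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        return dxr.reshape(B, C, L)


class UpConv2(Layer):
    """Transposed convolution, kernel 2 / stride 2: doubles the length."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.w = he_init(rng, (c_out, c_in, 2), fan_in=c_in)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self._register(self.w, self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        self._x = x
        # y[b, o, 2l + k] = sum_c w[o, c, k] x[b, c, l]
        t = np.einsum("bcl,ock->bolk", x, self.w, optimize=True)
        y = t.reshape(B, self.c_out, 2 * L) + self.b[:, None]
        return y.astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, O, L2 = dy.shape
        dyr = dy.reshape(B, O, L2 // 2, 2)
        self.grads[0] += np.einsum("bolk,bcl->ock", dyr, self._x, optimize=True)
        self.grads[1] += dy.sum(axis=(0, 2))
        return np.einsum("bolk,ock->bcl", dyr, self.w, optimize=True).astype(DTYPE, copy=False)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = he_init(rng, (n_out, n_in), fan_in=n_in)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self._register(self.w, self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0] += dy.T @ self._x
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.w


class ChannelAttention(Layer):
    """Squeeze-and-excitation style gate: global average pool -> bottleneck
    MLP -> sigmoid, producing one scale in (0, 1) per channel."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def sublayers(self) -> list[Layer]:
        return [self.fc1, self.fc2]

    def gate(self, x: np.ndarray) -> np.ndarray:
        """The (B, C) attention scales for input x; used by forward and tests."""
        s = x.mean(axis=2)
        h = self.fc1.forward(s)
        self._hmask = h > 0
        h = np.where(self._hmask, h, 0)
        return _sigmoid(self.fc2.forward(h))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._a = self.gate(x)
        return x * self._a[:, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, a = self._x, self._a
        L = x.shape[2]
        da = (dy * x).sum(axis=2)
        dz2 = (da * a * (1.0 - a)).astype(DTYPE)
        dh = self.fc2.backward(dz2)
        dh = np.where(self._hmask, dh, 0)
        ds = self.fc1.backward(dh)
        return dy * a[:, :, None] + (ds / L)[:, :, None]


class SpatialAttention(Layer):
    """Per-position gate: channel mean & max maps -> conv -> sigmoid scale."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv1d(2, 1, kernel, rng)

    def sublayers(self) -> list[Layer]:
        return [self.conv]

    def gate(self, x: np.ndarray) -> np.ndarray:
        """The (B, 1, L) attention scales for input x."""
        mean_map = x.mean(axis=1, keepdims=True)
        self._argmax = x.argmax(axis=1)
        max_map = x.max(axis=1, keepdims=True)
        m = np.concatenate([mean_map, max_map], axis=1).astype(DTYPE)
        return _sigmoid(self.conv.forward(m))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._a = self.gate(x)
        return x * self._a

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, a = self._x, self._a
        C = x.shape[1]
        da = (dy * x).sum(axis=1, keepdims=True)
        dz = (da * a * (1.0 - a)).astype(DTYPE)
        dm = self.conv.backward(dz)
        dx = dy * a
        dx += dm[:, 0:1, :] / C
        # scatter the max-map gradient to the argmax channel per position
        B, L = self._argmax.shape
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, self._argmax[:, None, :], dm[:, 1:2, :], axis=1)
        return dx + dmax


class ConvBlock(Layer):
    """conv-ReLU-conv-ReLU, optionally refined by channel then spatial attention."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 attention: bool = True, reduction: int = 8, sa_kernel: int = 7):
        super().__init__()
        self.layers: list[Layer] = [
            Conv1d(c_in, c_out, kernel, rng), ReLU(),
            Conv1d(c_out, c_out, kernel, rng), ReLU(),
        ]
        if attention:
            self.layers.append(ChannelAttention(c_out, reduction, rng))
            self.layers.append(SpatialAttention(sa_kernel, rng))

    def sublayers(self) -> list[Layer]:
        return self.layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
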