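"""Layers with explicit forward/backward passes on float32 arrays.

Array layout is channels-last: 1D activations are (N, L, C), 2D
activations are (N, H, W, C).  Convolutions are computed as a sum of
shifted GEMMs (one per kernel offset), which keeps all compute in BLAS
without an im2col copy.
"""

from __future__ import annotations

import numpy as np


class ShapeError(ValueError):
    """Raised when a layer cannot accept the given input shape."""


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base layer: stateless unless it owns parameters."""

    _CACHED = ("_xp", "_col", "_x", "_mask", "_steps", "_out", "_meta",
               "_in_shape", "_l_out", "_shape")

    def params(self) -> list[str]:
        return []

    def release(self) -> None:
        """Drop tensors cached for the backward pass (after inference)."""
        for attr in self._CACHED:
            self.__dict__.pop(attr, None)

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1D convolution, stride 1, padding 'same' or 'valid'."""

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: str = "same"):
        if padding not in ("same", "valid"):
            raise ShapeError(f"unknown padding {padding!r}")
        if kernel < 1:
            raise ShapeError("kernel must be >= 1")
        self.c_in, self.c_out, self.kernel, self.padding = c_in, c_out, kernel, padding
        self.W = np.zeros((kernel, c_in, c_out), dtype=np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return ["W", "b"]

    def initialize(self, rng):
        self.W = _he_init(rng, self.W.shape, self.kernel * self.c_in)
        self.b = np.zeros(self.c_out, dtype=np.float32)

    def out_length(self, length: int) -> int:
        if self.padding == "same":
            return length
        out = length - self.kernel + 1
        if out < 1:
            raise ShapeError(
                f"kernel {self.kernel} exceeds input length {length} (valid padding)"
            )
        return out

    def forward(self, x, *, training=False, rng=None):
        n, length, c = x.shape
        if c != self.c_in:
            raise ShapeError(f"expected {self.c_in} channels, got {c}")
        if self.padding == "same":
            pad_l = (self.kernel - 1) // 2
            pad_r = self.kernel - 1 - pad_l
            x = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        l_out = self.out_length(length)
        xp = np.ascontiguousarray(x)
        self._xp = xp
        self._l_out = l_out
        if self.kernel * c <= 32:
            # thin input (e.g. the single-channel first layer): a small
            # im2col gather plus one GEMM beats per-offset shift-adds
            win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
            col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
                n * l_out, self.kernel * c
            )
            self._col = col
            y = col @ self.W.reshape(self.kernel * c, self.c_out)
            y += self.b
            return y.reshape(n, l_out, self.c_out)
        # wide input: one contiguous GEMM per kernel offset, shift-added
        # into the output (keeps BLAS on contiguous operands, no gather)
        self._col = None
        l_pad = xp.shape[1]
        x2d = xp.reshape(n * l_pad, c)
        y = np.empty((n, l_out, self.c_out),
                     dtype=np.result_type(xp.dtype, self.W.dtype))
        y[:] = self.b
        for k in range(self.kernel):
            z = (x2d @ self.W[k]).reshape(n, l_pad, self.c_out)
            y += z[:, k : k + l_out, :]
        return y

    def backward(self, grad):
        xp, l_out = self._xp, self._l_out
        n, l_pad, c = xp.shape
        self.db = grad.sum(axis=(0, 1))
        g2d = np.ascontiguousarray(grad).reshape(n * l_out, self.c_out)
        if self._col is not None:
            self.dW = (self._col.T @ g2d).reshape(self.W.shape)
            dcol = (g2d @ self.W.reshape(-1, self.c_out).T).reshape(
                n, l_out, self.kernel, c
            )
            dx = np.zeros_like(xp)
            for k in range(self.kernel):
                dx[:, k : k + l_out, :] += dcol[:, :, k, :]
        else:
            x2d = xp.reshape(n * l_pad, c)
            # dW[k] via a zero-embedded copy of the gradient so the GEMM
            # runs on contiguous operands
            gp = np.zeros((n, l_pad, self.c_out), dtype=grad.dtype)
            dx = np.zeros_like(xp)
            for k in range(self.kernel):
                gp[:] = 0.0
                gp[:, k : k + l_out, :] = grad
                self.dW[k] = x2d.T @ gp.reshape(n * l_pad, self.c_out)
                dx[:, k : k + l_out, :] += (g2d @ self.W[k].T).reshape(n, l_out, c)
        if self.padding == "same":
            pad_l = (self.kernel - 1) // 2
            dx = dx[:, pad_l : pad_l + l_out, :]
        return dx


class Conv2D(Layer):
    """2D convolution with kernel (rows, cols), stride 1.

    For fingerprint matrices the row axis is the (small) fingerprint-type
    axis and the column axis runs along the 1024 bit positions.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 padding: str = "same"):
        if padding not in ("same", "valid"):
            raise ShapeError(f"unknown padding {padding!r}")
        self.c_in, self.c_out = c_in, c_out
        self.kh, self.kw = kernel
        if self.kh < 1 or self.kw < 1:
            raise ShapeError("kernel extents must be >= 1")
        self.padding = padding
        self.W = np.zeros((self.kh, self.kw, c_in, c_out), dtype=np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return ["W", "b"]

    def initialize(self, rng):
        self.W = _he_init(rng, self.W.shape, self.kh * self.kw * self.c_in)
        self.b = np.zeros(self.c_out, dtype=np.float32)

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        if self.padding == "same":
            return h, w
        oh, ow = h - self.kh + 1, w - self.kw + 1
        if oh < 1 or ow < 1:
            raise ShapeError(
                f"kernel ({self.kh},{self.kw}) exceeds input ({h},{w}) "
                "with valid padding"
            )
        return oh, ow

    def forward(self, x, *, training=False, rng=None):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ShapeError(f"expected {self.c_in} channels, got {c}")
        if self.padding == "valid" and (self.kh > h or self.kw > w):
            raise ShapeError(
                f"kernel ({self.kh},{self.kw}) exceeds input ({h},{w})"
            )
        if self.padding == "same":
            ph_l = (self.kh - 1) // 2
            ph_r = self.kh - 1 - ph_l
            pw_l = (self.kw - 1) // 2
            pw_r = self.kw - 1 - pw_l
            x = np.pad(x, ((0, 0), (ph_l, ph_r), (pw_l, pw_r), (0, 0)))
        oh, ow = self.out_shape(h, w)
        self._x = x
        self._oshape = (oh, ow)
        y = np.broadcast_to(self.b, (n, oh, ow, self.c_out)).copy()
        for i in range(self.kh):
            for j in range(self.kw):
                y += x[:, i : i + oh, j : j + ow, :] @ self.W[i, j]
        return y

    def backward(self, grad):
        x = self._x
        oh, ow = self._oshape
        self.db = grad.sum(axis=(0, 1, 2))
        dx = np.zeros_like(x)
        for i in range(self.kh):
            for j in range(self.kw):
                xs = x[:, i : i + oh, j : j + ow, :]
                self.dW[i, j] = np.tensordot(xs, grad, axes=([0, 1, 2], [0, 1, 2]))
                dx[:, i : i + oh, j : j + ow, :] += grad @ self.W[i, j].T
        if self.padding == "same":
            ph_l = (self.kh - 1) // 2
            pw_l = (self.kw - 1) // 2
            dx = dx[:, ph_l : ph_l + oh, pw_l : pw_l + ow, :]
        return dx


class ReLU(Layer):
    """Rectifier; clips its input buffer in place (inputs are always
    freshly-allocated activations of the preceding layer)."""

    def forward(self, x, *, training=False, rng=None):
        out = np.maximum(x, 0.0, out=x)
        self._out = out
        return out

    def backward(self, grad):
        grad *= self._out > 0
        return grad


def _pair_pool(x: np.ndarray, axis: int):
    """Window-2 stride-2 max along ``axis``; ties go to the earlier element."""
    length = x.shape[axis]
    l_out = length // 2
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, 2 * l_out, 2)
    a = x[tuple(sl)]
    sl[axis] = slice(1, 2 * l_out, 2)
    b = x[tuple(sl)]
    mask = a >= b
    return np.where(mask, a, b), mask


def _pair_unpool(grad: np.ndarray, mask: np.ndarray, in_shape, axis: int):
    dx = np.zeros(in_shape, dtype=grad.dtype)
    l_out = grad.shape[axis]
    sl = [slice(None)] * grad.ndim
    sl[axis] = slice(0, 2 * l_out, 2)
    np.multiply(grad, mask, out=dx[tuple(sl)])
    sl[axis] = slice(1, 2 * l_out, 2)
    np.multiply(grad, ~mask, out=dx[tuple(sl)])
    return dx


class MaxPool1D(Layer):
    """Max pooling with window 2, stride 2; a trailing odd element is dropped."""

    def __init__(self, pool: int = 2):
        if pool != 2:
            raise ShapeError("only pool size 2 is supported")
        self.pool = pool

    def forward(self, x, *, training=False, rng=None):
        if x.shape[1] // 2 < 1:
            raise ShapeError(f"input length {x.shape[1]} too short to pool")
        self._in_shape = x.shape
        out, self._mask = _pair_pool(x, axis=1)
        return out

    def backward(self, grad):
        return _pair_unpool(grad, self._mask, self._in_shape, axis=1)


class MaxPool2D(Layer):
    """2x2 max pooling; the row axis stops being pooled once it reaches 1."""

    def __init__(self, pool: tuple[int, int] = (2, 2)):
        self.pool = pool

    def forward(self, x, *, training=False, rng=None):
        n, h, w, c = x.shape
        pool_h = h >= self.pool[0]
        pool_w = w >= self.pool[1]
        self._steps = []
        out = x
        if pool_w:
            shape_w = out.shape
            out, mask = _pair_pool(out, axis=2)
            self._steps.append((2, mask, shape_w))
        if pool_h:
            shape_h = out.shape
            out, mask = _pair_pool(out, axis=1)
            self._steps.append((1, mask, shape_h))
        return out

    def backward(self, grad):
        for axis, mask, in_shape in reversed(self._steps):
            grad = _pair_unpool(grad, mask, in_shape, axis)
        return grad


class Flatten(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int):
        self.n_in, self.n_out = n_in, n_out
        self.W = np.zeros((n_in, n_out), dtype=np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return ["W", "b"]

    def initialize(self, rng):
        self.W = _he_init(rng, self.W.shape, self.n_in)
        self.b = np.zeros(self.n_out, dtype=np.float32)

    def forward(self, x, *, training=False, rng=None):
        if x.shape[1] != self.n_in:
            raise ShapeError(f"expected {self.n_in} features, got {x.shape[1]}")
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ShapeError(f"dropout probability must be in [0,1), got {p}")
        self.p = p

    def forward(self, x, *, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ShapeError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask
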