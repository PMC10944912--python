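"""Minimal NumPy neural-network layers with hand-written backward passes.

Only what the expression CNN needs: same-padding 1-D convolution,
non-overlapping max-pooling, dense layers, ReLU, inverted dropout, and an
Adam optimizer. Convolution is implemented as an im2col matrix product; the
backward pass reconstructs input gradients with k slice-adds, so everything
stays in BLAS-friendly matmuls. All layers cache what their backward pass
needs from the most recent forward call.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []


class Conv1DSame(Layer):
    """1-D convolution over (N, C_in, L), same padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel))
        self.w = w.astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _, length = x.shape
        k = self.kernel
        pad_l = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad_l, k - 1 - pad_l)))
        # (N, C_in, L, k) -> (N, L, C_in * k)
        win = sliding_window_view(xp, k, axis=2)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            n, length, self.c_in * k
        )
        self._cols = cols
        self._in_len = length
        wm = self.w.reshape(self.c_out, -1)
        out = cols @ wm.T + self.b
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        n, _, length = dout.shape
        k = self.kernel
        pad_l = (k - 1) // 2
        wm = self.w.reshape(self.c_out, -1)
        dmat = dout.transpose(0, 2, 1)  # (N, L, C_out)
        cols = self._cols
        dwm = dmat.reshape(-1, self.c_out).T @ cols.reshape(-1, cols.shape[2])
        self.grads[0][...] = dwm.reshape(self.w.shape)
        self.grads[1][...] = dout.sum(axis=(0, 2))
        if not need_input_grad:  # first layer: input gradient is never used
            return None
        dcols = dmat @ wm  # (N, L, C_in * k)
        dcols = dcols.reshape(n, length, self.c_in, k).transpose(0, 2, 1, 3)
        dxp = np.zeros((n, self.c_in, length + k - 1), dtype=DTYPE)
        for j in range(k):
            dxp[:, :, j : j + length] += dcols[:, :, :, j]
        return dxp[:, :, pad_l : pad_l + self._in_len]


class MaxPool1D(Layer):
    """Non-overlapping max-pool of width p; trailing remainder is dropped."""

    def __init__(self, width: int):
        super().__init__()
        self.width = width
        self._argmax: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        p = self.width
        lp = (length // p) * p
        if lp == 0:
            raise ValueError(f"pool width {p} exceeds input length {length}")
        y = x[:, :, :lp].reshape(n, c, lp // p, p)
        self._argmax = y.argmax(axis=3)
        self._in_len = length
        return y.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, lo = dout.shape
        p = self.width
        dxr = np.zeros((n, c, lo, p), dtype=DTYPE)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=3)
        dx = np.zeros((n, c, self._in_len), dtype=DTYPE)
        dx[:, :, : lo * p] = dxr.reshape(n, c, lo * p)
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(DTYPE, copy=False)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.w = w.astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class Dropout(Layer):
    """Inverted dropout; active only when the forward pass is in train mode."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            p -= (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)
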