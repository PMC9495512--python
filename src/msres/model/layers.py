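"""Numpy building blocks of the executable network.

Each layer implements ``forward`` (caching what backward needs) and
``backward`` (accumulating parameter gradients, returning the input
gradient).  Convolutions are evaluated as a single GEMM over an im2col
matrix, which is what keeps CPU training of the full model practical; the
im2col view is re-materialized in backward instead of cached, trading a
cheap copy for a threefold cut in activation memory.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg.blas import dgemm, sgemm

from ._kernels import maxpool_bwd, maxpool_fwd, relu_bwd


def _gemm(dtype):
    return sgemm if dtype == np.float32 else dgemm

__all__ = [
    "Param",
    "StemConv1d",
    "SameConv1d",
    "ReLU",
    "MaxPool1d",
    "Dense",
    "Dropout",
    "glorot_uniform",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


def glorot_uniform(shape, fan_in: int, fan_out: int, rng, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class StemConv1d:
    """Valid convolution of a single-channel signal: (B, L) -> (B, Lout, F).

    No activation follows the stem; it feeds the first residual block's
    shortcut directly.
    """

    def __init__(self, kernel: int, filters: int, stride: int, rng, dtype=np.float32):
        self.kernel = kernel
        self.stride = stride
        self.filters = filters
        self.w = Param(glorot_uniform((kernel, filters), kernel, kernel * filters, rng, dtype))
        self.b = Param(np.zeros(filters, dtype=dtype))
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def _cols(self, x):
        win = sliding_window_view(x, self.kernel, axis=1)[:, :: self.stride]
        return np.ascontiguousarray(win).reshape(-1, self.kernel)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B = x.shape[0]
        cols = self._cols(x)
        self._cache = x
        y = cols @ self.w.data
        return y.reshape(B, -1, self.filters) + self.b.data

    def backward(self, dy: np.ndarray) -> None:
        x = self._cache
        dyf = dy.reshape(-1, self.filters)
        self.w.grad += self._cols(x).T @ dyf
        self.b.grad += dyf.sum(axis=0)
        return None  # input layer: no upstream gradient needed


class SameConv1d:
    """Same-padded stride-1 convolution: (B, L, C) -> (B, L, F), odd kernel.

    Evaluated without im2col: the batch is viewed as one flat (B*L, C)
    signal and each kernel tap contributes one shifted GEMM, accumulated
    in place via BLAS.  Rows where a shift would cross a record boundary
    (where zero padding applies) are corrected afterwards; only
    (B-1) * (kernel-1) rows per tap need fixing, so the correction is
    negligible next to the main GEMMs.
    """

    def __init__(self, kernel: int, in_channels: int, filters: int, rng, dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("SameConv1d requires an odd kernel")
        self.kernel = kernel
        self.in_channels = in_channels
        self.filters = filters
        self.pad = kernel // 2
        fan_in = kernel * in_channels
        self.w = Param(
            glorot_uniform((kernel, in_channels, filters), fan_in, kernel * filters, rng, dtype)
        )
        self.b = Param(np.zeros(filters, dtype=dtype))
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def _boundary_rows(self, B: int, L: int, off: int):
        """Flat row indices whose tap-``off`` source lies in a neighboring record."""
        if off < 0:
            ls = np.arange(min(-off, L))
            bs = np.arange(1, B)
        else:
            ls = np.arange(max(L - off, 0), L)
            bs = np.arange(0, B - 1)
        if len(ls) == 0 or len(bs) == 0:
            return np.empty(0, dtype=np.int64)
        return (bs[:, None] * L + ls[None, :]).ravel()

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        x2 = np.ascontiguousarray(x).reshape(B * L, C)
        N = B * L
        y = np.zeros((N, self.filters), dtype=x2.dtype)
        gemm = _gemm(x2.dtype)
        for j in range(self.kernel):
            off = j - self.pad
            a, b = max(0, -off), N - max(0, off)
            if b <= a:
                continue
            # y[a:b] += x2[a+off : b+off] @ W_j, in place, no copies
            gemm(1.0, self.w.data[j].T, x2[a + off : b + off].T, 1.0, y[a:b].T,
                 overwrite_c=1)
            rows = self._boundary_rows(B, L, off)
            if len(rows):
                y[rows] -= x2[rows + off] @ self.w.data[j]
        y += self.b.data
        self._cache = (x2, (B, L))
        return y.reshape(B, L, self.filters)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2, (B, L) = self._cache
        C = self.in_channels
        N = B * L
        dyf = np.ascontiguousarray(dy).reshape(N, self.filters)
        dx2 = np.zeros((N, C), dtype=dyf.dtype)
        gemm = _gemm(dyf.dtype)
        for j in range(self.kernel):
            off = j - self.pad
            a, b = max(0, -off), N - max(0, off)
            if b <= a:
                continue
            # dW_j += x2[a+off:b+off].T @ dyf[a:b]
            gemm(1.0, dyf[a:b].T, x2[a + off : b + off].T, 1.0, self.w.grad[j].T,
                 trans_b=1, overwrite_c=1)
            # dx2[a+off:b+off] += dyf[a:b] @ W_j.T
            gemm(1.0, self.w.data[j].T, dyf[a:b].T, 1.0, dx2[a + off : b + off].T,
                 trans_a=1, overwrite_c=1)
            rows = self._boundary_rows(B, L, off)
            if len(rows):
                dyr = dyf[rows]
                self.w.grad[j] -= x2[rows + off].T @ dyr
                dx2[rows + off] -= dyr @ self.w.data[j].T
        self.b.grad += dyf.sum(axis=0)
        return dx2.reshape(B, L, C)


class ReLU:
    def __init__(self):
        self._out = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.maximum(x, 0)
        self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if dy.dtype == self._out.dtype and self._out.flags.c_contiguous:
            return relu_bwd(dy, self._out)
        return dy * (self._out > 0)


class MaxPool1d:
    """Valid max-pool over the length axis: (B, L, C) -> (B, Lout, C)."""

    def __init__(self, size: int = 5, stride: int = 2):
        self.size = size
        self.stride = stride
        self._cache = None

    def out_len(self, n: int) -> int:
        if n < self.size:
            raise ValueError(f"pool of size {self.size} applied to length {n}")
        return (n - self.size) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, idx = maxpool_fwd(np.ascontiguousarray(x), self.size, self.stride)
        self._cache = (idx, x.shape[1])
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, L = self._cache
        return maxpool_bwd(np.ascontiguousarray(dy), idx, L, self.size, self.stride)


class Dense:
    def __init__(self, in_features: int, units: int, rng, dtype=np.float32):
        self.w = Param(glorot_uniform((in_features, units), in_features, units, rng, dtype))
        self.b = Param(np.zeros(units, dtype=dtype))
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.w.data + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.w.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.data.T


class Dropout:
    """Inverted dropout; identity when evaluating or when rate is zero."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        self._mask = keep
        return x * keep

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask
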