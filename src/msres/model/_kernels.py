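"""Max-pool inner loops, JIT-compiled when numba is available.

The argmax gather and scatter dominate the non-GEMM cost of training; the
pure-numpy fallbacks are mathematically identical and are used
automatically when numba is missing.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _maxpool_fwd_jit(x, p, s):
    B, L, C = x.shape
    n = (L - p) // s + 1
    out = np.empty((B, n, C), dtype=x.dtype)
    idx = np.empty((B, n, C), dtype=np.int8)
    for b in range(B):
        for w in range(n):
            st = w * s
            for c in range(C):
                best = x[b, st, c]
                bi = 0
                for t in range(1, p):
                    v = x[b, st + t, c]
                    if v > best:
                        best = v
                        bi = t
                out[b, w, c] = best
                idx[b, w, c] = bi
    return out, idx


def _maxpool_fwd_np(x, p, s):
    win = sliding_window_view(x, p, axis=1)[:, ::s]  # (B, n, C, p)
    return win.max(axis=3), win.argmax(axis=3).astype(np.int8)


@njit(cache=True)
def _maxpool_bwd_jit(dy, idx, L, p, s):
    B, n, C = dy.shape
    dx = np.zeros((B, L, C), dtype=dy.dtype)
    for b in range(B):
        for w in range(n):
            st = w * s
            for c in range(C):
                dx[b, st + idx[b, w, c], c] += dy[b, w, c]
    return dx


def _maxpool_bwd_np(dy, idx, L, p, s):
    B, n, C = dy.shape
    dx = np.zeros((B, L, C), dtype=dy.dtype)
    for t in range(p):
        dx[:, t : t + s * n : s, :] += dy * (idx == t)
    return dx


@njit(cache=True)
def _relu_bwd_jit(dy, out):
    dy = dy.ravel()
    out = out.ravel()
    dx = np.empty_like(dy)
    for i in range(dy.size):
        dx[i] = dy[i] if out[i] > 0 else 0.0
    return dx


def _relu_bwd_np(dy, out):
    return (dy * (out > 0)).ravel()


if HAVE_NUMBA:
    maxpool_fwd = _maxpool_fwd_jit
    maxpool_bwd = _maxpool_bwd_jit
    _relu_bwd = _relu_bwd_jit
else:  # pragma: no cover
    maxpool_fwd = _maxpool_fwd_np
    maxpool_bwd = _maxpool_bwd_np
    _relu_bwd = _relu_bwd_np


def relu_bwd(dy, out):
    """dy masked by (out > 0), allocation-minimal."""
    return _relu_bwd(np.ascontiguousarray(dy), out).reshape(dy.shape)
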