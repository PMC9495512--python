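"""Executable multiscale residual network with hand-written gradients.

The network mirrors the symbolic ledger of :mod:`msres.model.config`
exactly: parallel streams (stem convolution + residual blocks), flattened
and concatenated, then the dense head ending in a single logit.  The
sigmoid is applied by the caller (numerically fused with the cross-entropy
during training), so ``forward`` returns logits.

Residual block computation::

    h1 = relu(conv1(x))
    h2 = relu(conv2(h1))
    y  = maxpool(h2 + x)

i.e. an activation after each of the two convolutions, none after the add,
and a valid max-pool closing the block.
"""

from __future__ import annotations

import numpy as np

from .config import MsResConfig, count_parameters, trace_shapes
from .layers import Dense, Dropout, MaxPool1d, Param, ReLU, SameConv1d, StemConv1d

__all__ = ["MsResNet", "build_model", "residual_block_forward"]


class ResidualBlock:
    def __init__(self, kernel, channels, pool_size, pool_stride, rng, dtype):
        self.conv1 = SameConv1d(kernel, channels, channels, rng, dtype)
        self.relu1 = ReLU()
        self.conv2 = SameConv1d(kernel, channels, channels, rng, dtype)
        self.relu2 = ReLU()
        self.pool = MaxPool1d(pool_size, pool_stride)

    @property
    def params(self):
        return self.conv1.params + self.conv2.params

    def forward(self, x):
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.relu2.forward(self.conv2.forward(h))
        return self.pool.forward(h + x)

    def backward(self, dy):
        dsum = self.pool.backward(dy)
        dh = self.conv2.backward(self.relu2.backward(dsum))
        dx = self.conv1.backward(self.relu1.backward(dh))
        return dx + dsum  # identity shortcut carries the gradient too


class _Stream:
    def __init__(self, kernel, config: MsResConfig, rng, dtype):
        self.stem = StemConv1d(kernel, config.filters, config.stem_stride, rng, dtype)
        self.blocks = [
            ResidualBlock(config.block_kernel, config.filters,
                          config.pool_size, config.pool_stride, rng, dtype)
            for _ in range(config.n_blocks)
        ]

    @property
    def params(self):
        out = list(self.stem.params)
        for b in self.blocks:
            out.extend(b.params)
        return out

    def forward(self, x):
        h = self.stem.forward(x)
        for b in self.blocks:
            h = b.forward(h)
        self._out_shape = h.shape
        return h.reshape(h.shape[0], -1)

    def backward(self, dflat):
        dh = dflat.reshape(self._out_shape)
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        self.stem.backward(dh)


class MsResNet:
    """Trainable multiscale residual encoder + dense classification head."""

    def __init__(self, config: MsResConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        trace = trace_shapes(config)  # validates the cascade up front
        self.flatten_len = trace["flatten_len"]
        rng = np.random.default_rng(seed)
        self.streams = [_Stream(k, config, rng, dtype) for k in config.kernel_sizes]
        self.head: list = []
        fan_in = self.flatten_len
        self._dense = []
        self._relus = []
        self._drops = []
        for i, units in enumerate(config.dense_units):
            self._dense.append(Dense(fan_in, units, rng, dtype))
            self._relus.append(ReLU())
            if i < len(config.dense_units) - 1:
                self._drops.append(Dropout(config.dropout))
            fan_in = units
        self.out_layer = Dense(fan_in, 1, rng, dtype)

    # ---- parameters ----------------------------------------------------
    def parameters(self) -> list[Param]:
        out = []
        for s in self.streams:
            out.extend(s.params)
        for d in self._dense:
            out.extend(d.params)
        out.extend(self.out_layer.params)
        return out

    @property
    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    # ---- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Map a batch (B, input_len) of segments to logits (B,)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim != 2 or x.shape[1] != self.config.input_len:
            raise ValueError(
                f"expected input of shape (batch, {self.config.input_len}), got {x.shape}"
            )
        flats = [s.forward(x) for s in self.streams]
        h = np.concatenate(flats, axis=1)
        self._splits = np.cumsum([f.shape[1] for f in flats])[:-1]
        for i, dense in enumerate(self._dense):
            h = self._relus[i].forward(dense.forward(h))
            if i < len(self._drops):
                h = self._drops[i].forward(h, train, rng)
        return self.out_layer.forward(h)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.out_layer.backward(dlogits[:, None].astype(self.dtype))
        for i in reversed(range(len(self._dense))):
            if i < len(self._drops):
                dh = self._drops[i].backward(dh)
            dh = self._dense[i].backward(self._relus[i].backward(dh))
        pieces = np.split(dh, self._splits, axis=1)
        for stream, piece in zip(self.streams, pieces):
            stream.backward(np.ascontiguousarray(piece))

    # ---- inference -----------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Sigmoid class-1 probabilities, strictly inside (0, 1)."""
        x = np.asarray(x)
        out = np.empty(len(x), dtype=np.float64)
        for lo in range(0, len(x), batch_size):
            logits = self.forward(x[lo : lo + batch_size], train=False)
            out[lo : lo + len(logits)] = _sigmoid(logits.astype(np.float64))
        return out

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(x) >= threshold).astype(np.int64)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_model(config: MsResConfig | None = None, seed: int = 0,
                dtype=np.float32) -> MsResNet:
    """Build a seeded trainable network; its weight-array sizes equal
    :func:`msres.model.config.count_parameters` for the same config."""
    config = config or MsResConfig()
    model = MsResNet(config, seed=seed, dtype=dtype)
    expected = count_parameters(config)
    assert model.num_parameters == expected, (
        f"internal inconsistency: built {model.num_parameters} parameters, "
        f"ledger says {expected}"
    )
    return model


def residual_block_forward(
    x: np.ndarray,
    conv1_w: np.ndarray,
    conv1_b: np.ndarray,
    conv2_w: np.ndarray,
    conv2_b: np.ndarray,
    pool_size: int = 5,
    pool_stride: int = 2,
) -> np.ndarray:
    """Functional single residual block: relu-conv twice, add, max-pool.

    ``x`` is ``(L, C)`` or ``(B, L, C)``; conv weights are ``(kernel, C, C)``
    (or pre-flattened ``(kernel*C, C)``) with biases ``(C,)``.  With all-zero
    conv weights the output is exactly ``maxpool(x)`` — the identity
    shortcut survives.
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    B, L, C = x.shape
    if L < pool_size:
        raise ValueError(f"input length {L} < pool size {pool_size}")

    def _make(wa, ba):
        wa = np.asarray(wa, dtype=np.float64)
        if wa.ndim == 2:  # flattened (kernel*C, C) layout
            wa = wa.reshape(-1, C, wa.shape[1])
        kernel = wa.shape[0]
        conv = SameConv1d(kernel, C, C, np.random.default_rng(0), np.float64)
        conv.w.data = np.ascontiguousarray(wa)
        conv.b.data = np.asarray(ba, dtype=np.float64)
        return conv

    conv1, conv2 = _make(conv1_w, conv1_b), _make(conv2_w, conv2_b)
    h = np.maximum(conv1.forward(x), 0)
    h = np.maximum(conv2.forward(h), 0)
    y = MaxPool1d(pool_size, pool_stride).forward(h + x)
    return y[0] if squeeze else y
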