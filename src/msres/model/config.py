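"""Symbolic description of the multiscale residual encoder.

The architecture is a set of parallel streams, one per stem kernel width
(the "scale"): a stride-3 stem convolution, then a cascade of residual
blocks, each two same-padded 32-filter convolutions with an identity
shortcut followed by a valid max-pool of size 5 / stride 2.  The pooled
streams are concatenated, flattened, and fed through a 64-32-16 dense head
into a single sigmoid output.

This module computes the layer ledger — output shapes and exact trainable
parameter counts — without building the executable network, so the
arithmetic can be checked independently of any numerics:

* stem convolution (1 input channel, bias): ``k * F + F`` parameters,
  output length ``floor((L - k)/stride) + 1`` (valid);
* block convolution (F -> F channels, kernel q, bias): ``F^2 * q + F``,
  length-preserving;
* valid pooling: ``floor((L - p)/s) + 1``;
* dense layer (m -> u, bias): ``m * u + u``.

For the defaults (input 2,700; kernels 5, 7, 9; 7 blocks; 32 filters) every
stream ends at length 4, the flattened feature is 3 x 4 x 32 = 384 wide and
the total is 158,401 trainable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import ConfigurationError

__all__ = [
    "MsResConfig",
    "LayerInfo",
    "ModelGraph",
    "stem_conv_params",
    "block_conv_params",
    "trace_shapes",
    "count_parameters",
    "model_graph",
]


@dataclass(frozen=True)
class MsResConfig:
    """Architectural hyperparameters of the multiscale residual encoder."""

    kernel_sizes: tuple[int, ...] = (5, 7, 9)
    n_blocks: int = 7
    filters: int = 32
    stem_stride: int = 3
    block_kernel: int = 3
    pool_size: int = 5
    pool_stride: int = 2
    dense_units: tuple[int, ...] = (64, 32, 16)
    dropout: float = 0.25
    input_len: int = 2700

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernel_sizes", tuple(int(k) for k in self.kernel_sizes))
        object.__setattr__(self, "dense_units", tuple(int(u) for u in self.dense_units))
        if not self.kernel_sizes:
            raise ConfigurationError("kernel_sizes must be non-empty")
        for name in ("n_blocks", "filters", "stem_stride", "block_kernel",
                     "pool_size", "pool_stride", "input_len"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if any(k < 1 for k in self.kernel_sizes) or any(u < 1 for u in self.dense_units):
            raise ConfigurationError("kernel sizes and dense units must be >= 1")
        if self.block_kernel % 2 != 1:
            raise ConfigurationError("block_kernel must be odd (same-padded convolution)")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must lie in [0, 1)")

    @property
    def n_streams(self) -> int:
        return len(self.kernel_sizes)


def stem_conv_params(kernel: int, filters: int) -> int:
    """Trainable parameters of a stem convolution (1 input channel, bias)."""
    if kernel < 1 or filters < 1:
        raise ValueError("kernel and filters must be >= 1")
    return kernel * filters + filters


def block_conv_params(filters: int, block_kernel: int) -> int:
    """Trainable parameters of one residual-block convolution (F -> F, bias)."""
    if filters < 1 or block_kernel < 1:
        raise ValueError("filters and block_kernel must be >= 1")
    return filters * filters * block_kernel + filters


def _conv_out_len(n: int, kernel: int, stride: int) -> int:
    return (n - kernel) // stride + 1


def trace_shapes(config: MsResConfig) -> dict:
    """Per-stream length cascade of the encoder.

    Returns ``{"streams": {kernel: [(layer, length), ...]}, "final_lens":
    {kernel: int}, "flatten_len": int}``.  Raises ``ConfigurationError``
    naming the offending layer if any stage would drop below length 1.
    """
    streams: dict[int, list[tuple[str, int]]] = {}
    final_lens: dict[int, int] = {}
    for k in config.kernel_sizes:
        ledger: list[tuple[str, int]] = []
        if config.input_len < k:
            raise ConfigurationError(
                f"stream(kernel={k}): stem conv needs input >= {k}, got {config.input_len}"
            )
        n = _conv_out_len(config.input_len, k, config.stem_stride)
        ledger.append((f"stem_conv(k={k},s={config.stem_stride})", n))
        for b in range(1, config.n_blocks + 1):
            # Two same-padded convolutions + identity add: length-preserving.
            ledger.append((f"block{b}_conv1", n))
            ledger.append((f"block{b}_conv2", n))
            ledger.append((f"block{b}_add", n))
            if n < config.pool_size:
                raise ConfigurationError(
                    f"stream(kernel={k}) block{b}_pool: length {n} < pool size "
                    f"{config.pool_size}; the pooling cascade collapsed"
                )
            n = _conv_out_len(n, config.pool_size, config.pool_stride)
            ledger.append((f"block{b}_pool({config.pool_size},{config.pool_stride})", n))
        streams[k] = ledger
        final_lens[k] = n
    flatten_len = sum(final_lens[k] * config.filters for k in config.kernel_sizes)
    return {"streams": streams, "final_lens": final_lens, "flatten_len": flatten_len}


@dataclass(frozen=True)
class LayerInfo:
    name: str
    kind: str
    output_shape: tuple[int, ...]
    params: int
    activation: str = ""


@dataclass(frozen=True)
class ModelGraph:
    """Ordered layer ledger with shapes and exact parameter counts."""

    layers: tuple[LayerInfo, ...]
    flatten_len: int

    @property
    def total_parameters(self) -> int:
        return sum(layer.params for layer in self.layers)

    def stream_layers(self, kernel: int) -> list[LayerInfo]:
        prefix = f"stream{kernel}/"
        return [l for l in self.layers if l.name.startswith(prefix)]

    def to_text(self) -> str:
        lines = [f"{'layer':<28} {'kind':<12} {'shape':<14} {'params':>8} {'activation':<10}"]
        for l in self.layers:
            shape = "x".join(str(d) for d in l.output_shape)
            lines.append(f"{l.name:<28} {l.kind:<12} {shape:<14} {l.params:>8} {l.activation:<10}")
        lines.append(f"total trainable parameters: {self.total_parameters}")
        return "\n".join(lines)


def model_graph(config: MsResConfig) -> ModelGraph:
    """Build the full layer ledger for a configuration."""
    trace = trace_shapes(config)
    F = config.filters
    layers: list[LayerInfo] = [LayerInfo("input", "input", (config.input_len, 1), 0)]
    for k in config.kernel_sizes:
        ledger = trace["streams"][k]
        it = iter(ledger)
        name, n = next(it)
        layers.append(LayerInfo(f"stream{k}/{name}", "conv1d", (n, F),
                                stem_conv_params(k, F)))
        bp = block_conv_params(F, config.block_kernel)
        for name, n in it:
            if "conv" in name:
                layers.append(LayerInfo(f"stream{k}/{name}", "conv1d", (n, F), bp, "relu"))
            elif "add" in name:
                layers.append(LayerInfo(f"stream{k}/{name}", "add", (n, F), 0))
            else:
                layers.append(LayerInfo(f"stream{k}/{name}", "maxpool1d", (n, F), 0))
    flat = trace["flatten_len"]
    layers.append(LayerInfo("concatenate", "concat", (flat,), 0))
    layers.append(LayerInfo("flatten", "flatten", (flat,), 0))
    fan_in = flat
    for i, units in enumerate(config.dense_units, start=1):
        layers.append(LayerInfo(f"dense{i}", "dense", (units,), fan_in * units + units, "relu"))
        if i < len(config.dense_units):
            layers.append(LayerInfo(f"dropout{i}", "dropout", (units,), 0))
        fan_in = units
    layers.append(LayerInfo("output", "dense", (1,), fan_in + 1, "sigmoid"))
    return ModelGraph(tuple(layers), flat)


def count_parameters(config: MsResConfig) -> int:
    """Exact trainable-parameter count of the configured network."""
    return model_graph(config).total_parameters
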