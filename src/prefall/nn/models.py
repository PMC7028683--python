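"""The three classifier families and their symbolic shape traces.

All three consume a 256-sample × 6-channel window (three accelerometer +
three gyroscope axes at 200 Hz) and emit a 3-way softmax over
{non-fall, pre-impact fall, fall}.

* ``cnn`` — three blocks of [conv(k=3, 64 ch) → batch norm → ReLU →
  max-pool(k=3, s=2)], flatten, fully connected 1920→512→3.  With per-block
  convolution paddings (1, 0, 1) the temporal lengths run
  256 → 127 → 62 → 30, so the flattened width is 30·64 = 1920; this padding
  pattern is the unique one consistent with those dimensions and is the
  default.
* ``lstm`` — stacked LSTM layers over the raw sequence, final hidden state →
  ReLU → dropout → fully connected → softmax.
* ``convlstm`` — the hybrid: four conv blocks (width 64) compress the window
  to a short feature sequence which two stacked LSTM layers read; dropout
  between and after the recurrent layers; final-step head.  The default
  matches the tuning winner: width 64, 4 conv blocks, 2 LSTM layers,
  dropout 0.5.

``shape_trace`` computes every layer's output shape symbolically, without
allocating parameters; the test suite checks it against shapes measured on a
real forward pass.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..errors import ArchitectureError, ConfigError
from .core import (
    LSTM,
    Adam,
    BatchNorm1d,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    LastStep,
    Layer,
    MaxPool1d,
    ReLU,
    Sequential,
    Softmax,
)

__all__ = [
    "ModelConfig",
    "ShapeTrace",
    "Model",
    "build_model",
    "build_cnn",
    "build_lstm",
    "build_convlstm",
    "shape_trace",
]

FAMILIES = ("cnn", "lstm", "convlstm")


@dataclass
class ModelConfig:
    """Declarative architecture description for one model family."""

    family: str = "convlstm"
    width: int = 64              # conv channels and LSTM hidden size
    n_conv_blocks: int = 4
    n_lstm_layers: int = 2
    kernel_len: int = 3
    pool_len: int = 3
    pool_stride: int = 2
    conv_padding: tuple[int, ...] | None = None  # per-block; family default if None
    dropout: float = 0.5
    fc_hidden: int = 512         # cnn only
    n_classes: int = 3
    input_len: int = 256
    input_channels: int = 6

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}; known: {FAMILIES}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.n_classes != 3:
            raise ConfigError("the classifier is three-class by construction")
        if self.conv_padding is None:
            if self.family == "cnn":
                self.conv_padding = _default_cnn_padding(self.n_conv_blocks)
            else:
                self.conv_padding = tuple([1] * self.n_conv_blocks)
        else:
            self.conv_padding = tuple(self.conv_padding)
        if self.family != "lstm" and len(self.conv_padding) != self.n_conv_blocks:
            raise ConfigError(
                f"conv_padding has {len(self.conv_padding)} entries for "
                f"{self.n_conv_blocks} blocks"
            )

    @classmethod
    def cnn(cls, **kw) -> "ModelConfig":
        kw.setdefault("n_conv_blocks", 3)
        kw.setdefault("dropout", 0.0)
        return cls(family="cnn", **kw)

    @classmethod
    def lstm(cls, **kw) -> "ModelConfig":
        kw.setdefault("n_conv_blocks", 0)
        return cls(family="lstm", **kw)

    @classmethod
    def convlstm(cls, **kw) -> "ModelConfig":
        return cls(family="convlstm", **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_padding"] = list(self.conv_padding) if self.conv_padding else []
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("conv_padding") is not None:
            d["conv_padding"] = tuple(d["conv_padding"])
        return cls(**d)


def _default_cnn_padding(n_blocks: int) -> tuple[int, ...]:
    # (1, 0, 1) reproduces the canonical 256 -> 127 -> 62 -> 30 lengths;
    # extra blocks keep length through the convolution (padding 1).
    base = (1, 0, 1)
    if n_blocks <= 3:
        return base[:n_blocks]
    return base + tuple([1] * (n_blocks - 3))


#: Ordered (layer name, output length, output channels) triples.  Flat
#: feature vectors are reported with length 1, matching the "1 × F"
#: convention for fully connected inputs.
ShapeTrace = list[tuple[str, int, int]]


def _pool_out(t: int, k: int, s: int, name: str) -> int:
    if t < k:
        raise ArchitectureError(
            f"{name}: input length {t} shorter than pooling kernel {k}"
        )
    return (t - k) // s + 1


def _conv_out(t: int, k: int, p: int, name: str) -> int:
    t_out = t + 2 * p - k + 1
    if t_out < 1:
        raise ArchitectureError(
            f"{name}: input length {t} too short for kernel {k} with padding {p}"
        )
    return t_out


def shape_trace(config: ModelConfig) -> ShapeTrace:
    """Per-layer output shapes from layer arithmetic alone."""
    t, c = config.input_len, config.input_channels
    trace: ShapeTrace = [("input", t, c)]
    if config.family in ("cnn", "convlstm"):
        for i in range(config.n_conv_blocks):
            p = config.conv_padding[i]
            t = _conv_out(t, config.kernel_len, p, f"conv{i + 1}")
            trace.append((f"conv{i + 1}", t, config.width))
            trace.append((f"bn{i + 1}", t, config.width))
            trace.append((f"relu{i + 1}", t, config.width))
            t = _pool_out(t, config.pool_len, config.pool_stride, f"pool{i + 1}")
            trace.append((f"pool{i + 1}", t, config.width))
        c = config.width
    if config.family == "cnn":
        trace.append(("flatten", 1, t * c))
        trace.append(("fc1", 1, config.fc_hidden))
        trace.append(("relu_fc1", 1, config.fc_hidden))
        if config.dropout > 0:
            trace.append(("dropout_fc", 1, config.fc_hidden))
        trace.append(("fc2", 1, config.n_classes))
    else:
        for i in range(config.n_lstm_layers):
            trace.append((f"lstm{i + 1}", t, config.width))
            if i < config.n_lstm_layers - 1 and config.dropout > 0:
                trace.append((f"dropout{i + 1}", t, config.width))
        trace.append(("last_step", 1, config.width))
        if config.family == "lstm":
            trace.append(("relu_head", 1, config.width))
        if config.dropout > 0:
            trace.append(("dropout_head", 1, config.width))
        trace.append(("fc", 1, config.n_classes))
    trace.append(("softmax", 1, config.n_classes))
    return trace


def flatten_width(config: ModelConfig) -> int:
    """Width of the flattened feature vector entering the CNN's first FC layer."""
    trace = shape_trace(config)
    for name, _, chans in trace:
        if name == "flatten":
            return chans
    raise ArchitectureError(f"family {config.family!r} has no flatten stage")


class Model:
    """A built network: layers + the RNG that drives its dropout masks."""

    def __init__(self, config: ModelConfig, net: Sequential, seed: int) -> None:
        self.config = config
        self.net = net
        self.seed = seed

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(np.asarray(x, dtype=np.float64), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        out = [self.net.forward(x[i:i + batch_size], training=False)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=-1)

    def reseed_dropout(self, seed: int) -> None:
        """Make dropout masks reproducible for a training run."""
        rng = np.random.default_rng(seed)
        for layer in self.net.layers:
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(rng.integers(2 ** 31))

    # -- checkpointing ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data for p in self.params()}
        for layer in self.net.layers:
            if isinstance(layer, BatchNorm1d):
                state[f"{layer.name}.running_mean"] = layer.running_mean
                state[f"{layer.name}.running_var"] = layer.running_var
        return state

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, **self.state_arrays())
        meta = {"config": self.config.to_dict(), "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        model = build_model(ModelConfig.from_dict(meta["config"]), seed=meta["seed"])
        data = np.load(path)
        for p in model.params():
            p.data[...] = data[p.name]
        for layer in model.net.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = data[f"{layer.name}.running_mean"].copy()
                layer.running_var = data[f"{layer.name}.running_var"].copy()
        return model


def _conv_blocks(config: ModelConfig, rng: np.random.Generator) -> list[Layer]:
    layers: list[Layer] = []
    in_ch = config.input_channels
    for i in range(config.n_conv_blocks):
        layers.append(Conv1d(in_ch, config.width, config.kernel_len,
                             config.conv_padding[i], rng, name=f"conv{i + 1}"))
        layers.append(BatchNorm1d(config.width, name=f"bn{i + 1}"))
        layers.append(ReLU(name=f"relu{i + 1}"))
        layers.append(MaxPool1d(config.pool_len, config.pool_stride, name=f"pool{i + 1}"))
        in_ch = config.width
    return layers


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Instantiate a model; a pure function of (config, seed)."""
    # validate arithmetic before allocating anything
    trace = shape_trace(config)
    rng = np.random.default_rng(seed)
    layers: list[Layer]
    if config.family == "cnn":
        layers = _conv_blocks(config, rng)
        flat = next(ch for name, _, ch in trace if name == "flatten")
        layers.append(Flatten())
        layers.append(Dense(flat, config.fc_hidden, rng, name="fc1"))
        layers.append(ReLU(name="relu_fc1"))
        if config.dropout > 0:
            layers.append(Dropout(config.dropout, name="dropout_fc"))
        layers.append(Dense(config.fc_hidden, config.n_classes, rng, name="fc2"))
    else:
        layers = []
        in_f = config.input_channels
        if config.family == "convlstm":
            layers = _conv_blocks(config, rng)
            in_f = config.width
        for i in range(config.n_lstm_layers):
            layers.append(LSTM(in_f, config.width, rng, name=f"lstm{i + 1}"))
            in_f = config.width
            if i < config.n_lstm_layers - 1 and config.dropout > 0:
                layers.append(Dropout(config.dropout, name=f"dropout{i + 1}"))
        layers.append(LastStep())
        if config.family == "lstm":
            layers.append(ReLU(name="relu_head"))
        if config.dropout > 0:
            layers.append(Dropout(config.dropout, name="dropout_head"))
        layers.append(Dense(in_f, config.n_classes, rng, name="fc"))
    layers.append(Softmax())
    model = Model(config, Sequential(layers), seed)
    model.reseed_dropout(seed)
    return model


def build_cnn(config: ModelConfig | None = None, seed: int = 0) -> Model:
    config = config if config is not None else ModelConfig.cnn()
    if config.family != "cnn":
        raise ConfigError(f"build_cnn got family {config.family!r}")
    return build_model(config, seed)


def build_lstm(config: ModelConfig | None = None, seed: int = 0) -> Model:
    config = config if config is not None else ModelConfig.lstm()
    if config.family != "lstm":
        raise ConfigError(f"build_lstm got family {config.family!r}")
    return build_model(config, seed)


def build_convlstm(config: ModelConfig | None = None, seed: int = 0) -> Model:
    config = config if config is not None else ModelConfig.convlstm()
    if config.family != "convlstm":
        raise ConfigError(f"build_convlstm got family {config.family!r}")
    return build_model(config, seed)
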