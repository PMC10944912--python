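"""The multitask expression CNN.

Architecture: two (convolution -> ReLU -> max-pool) blocks over the 4 x L
one-hot promoter window, flattened and concatenated with the five mRNA
half-life features, then a fully connected head with linear outputs — one
output per prediction task (cell population or tissue). The multitask head
is a single linear layer; single-task models add one hidden layer. Dropout
is applied before each dense layer during training.

Defaults follow the promoter-CNN lineage this model descends from:
block 1 = 128 filters, width 6, pool 30; block 2 = 32 filters, width 9,
pool 10; dropout 0.5. All of it is configurable through :class:`ModelConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import DTYPE, Conv1DSame, Dense, Dropout, MaxPool1D, ReLU


@dataclass(frozen=True)
class ConvBlockSpec:
    filters: int
    kernel: int
    pool: int


DEFAULT_CONV_BLOCKS = (ConvBlockSpec(128, 6, 30), ConvBlockSpec(32, 9, 10))


@dataclass
class ModelConfig:
    """Hyperparameters defining one network; serialized with checkpoints."""

    up_len: int = 7000
    down_len: int = 3500
    conv_blocks: tuple[ConvBlockSpec, ...] = DEFAULT_CONV_BLOCKS
    fc_hidden: tuple[int, ...] = ()  # empty = multitask head (single FC layer)
    dropout: float = 0.5
    n_tasks: int = 1
    n_halflife: int = 5
    seed: int = 0

    @property
    def window_len(self) -> int:
        return self.up_len + self.down_len

    def __post_init__(self) -> None:
        self.conv_blocks = tuple(
            b if isinstance(b, ConvBlockSpec) else ConvBlockSpec(*b)
            for b in self.conv_blocks
        )
        if not self.conv_blocks:
            raise ValueError("need at least one convolution block")
        if self.n_tasks < 1:
            raise ValueError("n_tasks must be >= 1")
        for b in self.conv_blocks:
            if min(b.filters, b.kernel, b.pool) < 1:
                raise ValueError(f"non-positive width in conv block {b}")

    def flattened_size(self) -> int:
        length = self.window_len
        for b in self.conv_blocks:
            length //= b.pool
        if length == 0:
            raise ValueError(
                f"window of {self.window_len} bp collapses to size 0 after pooling"
            )
        return length * self.conv_blocks[-1].filters

    def to_dict(self) -> dict:
        return {
            "up_len": self.up_len,
            "down_len": self.down_len,
            "conv_blocks": [[b.filters, b.kernel, b.pool] for b in self.conv_blocks],
            "fc_hidden": list(self.fc_hidden),
            "dropout": self.dropout,
            "n_tasks": self.n_tasks,
            "n_halflife": self.n_halflife,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_blocks"] = tuple(ConvBlockSpec(*b) for b in d["conv_blocks"])
        d["fc_hidden"] = tuple(d["fc_hidden"])
        return cls(**d)


class ExpressionCNN:
    """Maps (one-hot window, half-life features) -> per-task expression."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.conv_layers: list = []
        c_in = 4
        for b in config.conv_blocks:
            self.conv_layers += [
                Conv1DSame(c_in, b.filters, b.kernel, rng),
                ReLU(),
                MaxPool1D(b.pool),
            ]
            c_in = b.filters
        config.flattened_size()  # validates pooling vs window length
        d_in = config.flattened_size() + config.n_halflife
        self.head: list = []
        for width in config.fc_hidden:
            self.head += [Dropout(config.dropout), Dense(d_in, width, rng), ReLU()]
            d_in = width
        self.head += [Dropout(config.dropout), Dense(d_in, config.n_tasks, rng)]
        self._flat_shape: tuple[int, int] | None = None

    @property
    def layers(self) -> list:
        return self.conv_layers + self.head

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def forward(
        self,
        x_seq: np.ndarray,
        x_hl: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        h = np.asarray(x_seq, dtype=DTYPE)
        for layer in self.conv_layers:
            h = layer.forward(h)
        n = h.shape[0]
        self._flat_shape = h.shape
        h = h.reshape(n, -1)
        h = np.concatenate([h, np.asarray(x_hl, dtype=DTYPE)], axis=1)
        for layer in self.head:
            if isinstance(layer, Dropout):
                h = layer.forward(h, train=train, rng=rng)
            else:
                h = layer.forward(h)
        return h

    def backward(self, dout: np.ndarray) -> None:
        h = dout.astype(DTYPE, copy=False)
        for layer in reversed(self.head):
            h = layer.backward(h)
        h = h[:, : -self.config.n_halflife]  # half-life inputs take no gradient
        h = h.reshape(self._flat_shape)
        for i, layer in reversed(list(enumerate(self.conv_layers))):
            if i == 0 and isinstance(layer, Conv1DSame):
                layer.backward(h, need_input_grad=False)
            else:
                h = layer.backward(h)

    def predict(self, x_seq: np.ndarray, x_hl: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x_seq.shape[0], batch):
            out.append(self.forward(x_seq[i : i + batch], x_hl[i : i + batch]))
        return np.concatenate(out, axis=0)


def build_model(config: ModelConfig) -> ExpressionCNN:
    """Construct an untrained network from its configuration."""
    return ExpressionCNN(config)
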