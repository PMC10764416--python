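"""Three-block 1-D convolutional classifier.

Architecture: 3 x [conv(ReLU) -> maxpool(2) -> dropout(0.2)] with kernel
sizes (7, 3, 3), then flatten -> dropout -> dense(10, ReLU) -> dense(1) with
a sigmoid read-out. Same-padding keeps 120 time steps mapping to 15 after
the three pooling stages. Trained with AdamW (lr 1e-3, weight decay 1e-3),
class-weighted binary cross-entropy, batch size 32, a fixed 30 epochs and no
early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dataio import ValidationError
from ..windowing import WindowDataset
from . import _nn
from .base import FittedModel, sample_weights, training_arrays


@dataclass
class CNNConfig:
    kernel_sizes: tuple[int, int, int] = (7, 3, 3)
    filters: tuple[int, int, int] = (16, 16, 16)
    pool_size: int = 2
    dropout: float = 0.2
    dense_units: int = 10
    epochs: int = 30
    learning_rate: float = 0.001
    batch_size: int = 32
    weight_decay: float = 0.001
    seed: int = 0


class CNNModel(FittedModel):
    family = "cnn"

    def __init__(self, config: CNNConfig, channel_names: tuple[str, ...], n_time: int):
        super().__init__(channel_names)
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
        )
        layers: list[_nn.Layer] = []
        in_ch = len(channel_names)
        L = n_time
        for k, f in zip(config.kernel_sizes, config.filters):
            layers += [
                _nn.Conv1d(in_ch, f, k, rng),
                _nn.ReLU(),
                _nn.MaxPool1d(config.pool_size),
                _nn.Dropout(config.dropout, self._dropout_rng),
            ]
            in_ch = f
            L //= config.pool_size
        layers += [
            _nn.Flatten(),
            _nn.Dropout(config.dropout, self._dropout_rng),
            _nn.Dense(in_ch * L, config.dense_units, rng),
            _nn.ReLU(),
            _nn.Dense(config.dense_units, 1, rng),
        ]
        self.net = _nn.Sequential(layers)

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.net.params())

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNModel":
        cfg = self.config
        w = sample_weights(y).astype(np.float32)
        Xc = np.ascontiguousarray(X.transpose(0, 2, 1), dtype=np.float32)  # (N, C, L)
        opt = _nn.AdamW(self.net.params(), lr=cfg.learning_rate,
                        weight_decay=cfg.weight_decay)
        shuffle_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0]
        )
        for _ in range(cfg.epochs):
            for idx in _nn.minibatches(len(y), cfg.batch_size, shuffle_rng):
                opt.zero_grad()
                z = self.net.forward(Xc[idx], train=True)[:, 0]
                _, dz = _nn.weighted_bce_with_logits(z, y[idx], w[idx])
                self.net.backward(dz[:, None])
                opt.step()
        return self

    def predict_proba(
        self, X: np.ndarray, channel_names: tuple[str, ...] | None = None
    ) -> np.ndarray:
        self.check_channels(X, channel_names)
        Xc = np.ascontiguousarray(X.transpose(0, 2, 1), dtype=np.float32)
        out = np.empty(len(Xc))
        for i in range(0, len(Xc), 1024):
            z = self.net.forward(Xc[i : i + 1024], train=False)[:, 0]
            out[i : i + 1024] = _nn.sigmoid(z)
        return out


def train_cnn(train: WindowDataset, config: CNNConfig | None = None) -> CNNModel:
    config = config or CNNConfig()
    X, y = training_arrays(train)
    if X.shape[1] % config.pool_size**3 != 0:
        raise ValidationError("window length must survive three pooling stages")
    model = CNNModel(config, train.channel_names, X.shape[1])
    return model.fit(X, y)
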