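"""Common classifier interface shared by all model families.

Every fitted model exposes ``predict_proba(X) -> p`` with ``p`` in [0, 1],
refuses inputs whose channel layout differs from the one it was trained on,
and is a deterministic function of (training data, config, seed).
"""

from __future__ import annotations

import numpy as np

from ..dataio import ValidationError
from ..windowing import WindowDataset


def compute_class_weights(y: np.ndarray) -> tuple[float, float]:
    """Balanced class weights w_c = N / (2 * N_c) for binary targets."""
    y = np.asarray(y)
    n = y.shape[0]
    n_pos = int(np.sum(y == 1))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute weights")
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


def sample_weights(y: np.ndarray) -> np.ndarray:
    w_neg, w_pos = compute_class_weights(y)
    return np.where(y == 1, w_pos, w_neg)


class FittedModel:
    """Base class: channel guard + probability contract."""

    family: str = "?"

    def __init__(self, channel_names: tuple[str, ...]):
        self.channel_names = tuple(channel_names)

    def check_channels(self, X: np.ndarray, channel_names: tuple[str, ...] | None) -> None:
        if X.ndim != 3 or X.shape[2] != len(self.channel_names):
            raise ValidationError(
                f"{self.family}: expected windows with {len(self.channel_names)} "
                f"channels, got array of shape {X.shape}"
            )
        if channel_names is not None and tuple(channel_names) != self.channel_names:
            raise ValidationError(
                f"{self.family}: channel layout mismatch — trained on "
                f"{self.channel_names}, given {tuple(channel_names)}"
            )

    def predict_proba(
        self, X: np.ndarray, channel_names: tuple[str, ...] | None = None
    ) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict_dataset(self, dataset: WindowDataset) -> np.ndarray:
        return self.predict_proba(dataset.X, dataset.channel_names)


def training_arrays(train: WindowDataset) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) for fitting: float32 windows, binary targets; rejects DISCARD
    windows and single-class data."""
    y = train.y()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("training data must contain both classes")
    return train.X.astype(np.float32), y
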