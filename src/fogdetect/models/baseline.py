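"""Spectral band-power baseline.

Trembling-type FOG concentrates power in the 3-8 Hz "freeze band" while
normal gait is dominated by the 0.5-3 Hz locomotor band, so the log ratio of
the two band powers (summed over channels) is a one-dimensional physiological
discriminant. It serves as a floor for the learned models and as a check
that the synthetic task is learnable at all.
"""

from __future__ import annotations

import numpy as np

from ..dataio import ValidationError
from ..windowing import WindowDataset
from . import _nn
from .base import FittedModel, training_arrays

LOCOMOTOR_BAND = (0.5, 3.0)
FREEZE_BAND = (3.0, 8.0)


def band_power(X: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Total spectral power of each window in a frequency band, summed over
    channels. X: (N, L, C)."""
    L = X.shape[1]
    spec = np.abs(np.fft.rfft(X, axis=1)) ** 2
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs < band[1])
    return spec[:, sel, :].sum(axis=(1, 2))


def freeze_index(X: np.ndarray, fs: float = 60.0) -> np.ndarray:
    """log((3-8 Hz power) / (0.5-3 Hz power)) per window."""
    hi = band_power(X, fs, FREEZE_BAND)
    lo = band_power(X, fs, LOCOMOTOR_BAND)
    return np.log((hi + 1e-12) / (lo + 1e-12))


class SpectralBaselineModel(FittedModel):
    """Monotone map of the freeze index to [0, 1] via train-set standardization."""

    family = "spectral_baseline"

    def __init__(self, channel_names: tuple[str, ...], fs: float = 60.0):
        super().__init__(channel_names)
        self.fs = fs
        self._mu: float | None = None
        self._sd: float = 1.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SpectralBaselineModel":
        s = freeze_index(X, self.fs)
        self._mu = float(s.mean())
        self._sd = float(s.std()) or 1.0
        return self

    def predict_proba(
        self, X: np.ndarray, channel_names: tuple[str, ...] | None = None
    ) -> np.ndarray:
        self.check_channels(X, channel_names)
        if self._mu is None:
            raise ValidationError("model has not been fitted")
        return _nn.sigmoid((freeze_index(X, self.fs) - self._mu) / self._sd)


def train_spectral_baseline(train: WindowDataset) -> SpectralBaselineModel:
    X, y = training_arrays(train)
    return SpectralBaselineModel(train.channel_names).fit(X, y)
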