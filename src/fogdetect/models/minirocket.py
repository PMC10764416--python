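"""MiniRocket transform with a gradient-trained logistic head.

The transform convolves each window with the 84 two-valued kernels of length
9 (every choice of 3 taps with weight +2, the remaining 6 taps weight -1, so
each kernel sums to zero), at an exponentially spaced set of dilations capped
at 32 per kernel, and pools each convolution with PPV (proportion of positive
values) against biases drawn from quantiles of the convolution outputs on a
training subsample. With the default feature budget of 10,000 the transform
yields floor(10000 / 84) = 119 features per kernel, 9,996 features in total,
and the logistic head therefore has 9,996 coefficients.

Multichannel windows are handled by random channel combinations fixed by the
seed: the kernels are split into groups of 14 and each (group, dilation)
pair sums a random power-of-two-sized subset of channels before convolving,
which lets one matrix product evaluate a whole kernel group at once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ..dataio import ValidationError
from ..windowing import WindowDataset
from . import _nn
from .base import FittedModel, sample_weights, training_arrays

KERNEL_LENGTH = 9
N_KERNELS = 84  # C(9, 3) two-valued kernels with three +2 taps
KERNEL_GROUP_SIZE = 14  # kernels per shared channel combination


@dataclass
class MiniRocketConfig:
    feature_budget: int = 10_000
    max_dilations_per_kernel: int = 32
    bias_sample_size: int = 2**11
    head_epochs: int = 10
    head_learning_rate: float = 0.001
    head_batch_size: int = 256
    seed: int = 0


def kernel_weight_matrix() -> np.ndarray:
    """(84, 9) matrix of two-valued kernel weights: +2 at 3 taps, -1 elsewhere."""
    W = -np.ones((N_KERNELS, KERNEL_LENGTH))
    for row, taps in enumerate(itertools.combinations(range(KERNEL_LENGTH), 3)):
        W[row, list(taps)] = 2.0
    return W


def fit_dilations(
    n_time: int, feature_budget: int, max_dilations_per_kernel: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exponentially spaced dilations and the per-kernel feature allocation.

    Returns ``(dilations, features_per_dilation)`` with
    ``features_per_dilation.sum() == feature_budget // 84``, so the total
    feature count is an exact multiple of the kernel count. The largest
    dilation stretches the 9-tap receptive field across the whole window.
    """
    per_kernel = feature_budget // N_KERNELS
    true_max = min(max_dilations_per_kernel, per_kernel)
    multiplier = per_kernel / true_max
    max_exponent = np.log2((n_time - 1) / (KERNEL_LENGTH - 1))
    dilations, counts = np.unique(
        np.logspace(0, max_exponent, true_max, base=2).astype(np.int64),
        return_counts=True,
    )
    features = (counts * multiplier).astype(np.int64)
    remainder = per_kernel - int(features.sum())
    i = 0
    while remainder > 0:
        features[i] += 1
        remainder -= 1
        i = (i + 1) % len(features)
    return dilations, features


def dilated_convolution(
    x: np.ndarray, weights: np.ndarray, dilation: int
) -> np.ndarray:
    """Zero-padded 'same' dilated convolution of a (N, L) series batch with a
    length-9 kernel; tap j acts at offset (j - 4) * dilation."""
    N, L = x.shape
    pad = (KERNEL_LENGTH // 2) * dilation
    xp = np.zeros((N, L + 2 * pad), dtype=np.float64)
    xp[:, pad : pad + L] = x
    out = np.zeros((N, L), dtype=np.float64)
    for j in range(KERNEL_LENGTH):
        out += weights[j] * xp[:, j * dilation : j * dilation + L]
    return out


def ppv(conv: np.ndarray, bias: float) -> np.ndarray:
    """Proportion of positive values of (conv - bias) along time; in [0, 1]."""
    return (conv > bias).mean(axis=-1)


class MiniRocketTransform:
    """Stateful transform: channel combinations and biases fixed at fit time.

    Feature columns are ordered kernel-major: all features of kernel 0
    (dilation-major, biases in ascending quantile order), then kernel 1, ...
    """

    def __init__(self, config: MiniRocketConfig | None = None):
        self.config = config or MiniRocketConfig()
        self._fitted = False

    @property
    def n_features(self) -> int:
        if not self._fitted:
            raise ValidationError("transform must be fitted before use")
        return int(self._n_features)

    # -- structure ---------------------------------------------------------

    def _groups(self) -> list[np.ndarray]:
        idx = np.arange(N_KERNELS)
        return [idx[i : i + KERNEL_GROUP_SIZE] for i in range(0, N_KERNELS, KERNEL_GROUP_SIZE)]

    def channel_set(self, kernel: int, dilation_index: int) -> np.ndarray:
        group = kernel // KERNEL_GROUP_SIZE
        return self.channel_sets[(dilation_index, group)]

    def _column(self, kernel: int, dilation_index: int) -> int:
        per_kernel = int(self.features_per_dilation.sum())
        return kernel * per_kernel + int(self.features_per_dilation[:dilation_index].sum())

    def _shifted_stack(self, X: np.ndarray, dilation: int, chans: np.ndarray) -> np.ndarray:
        """(9, N*L) matrix of dilated shifts of the channel-summed series."""
        xs = X[:, :, chans].sum(axis=2)
        N, L = xs.shape
        pad = (KERNEL_LENGTH // 2) * dilation
        xp = np.zeros((N, L + 2 * pad), dtype=np.float64)
        xp[:, pad : pad + L] = xs
        S = np.empty((KERNEL_LENGTH, N, L), dtype=np.float64)
        for j in range(KERNEL_LENGTH):
            S[j] = xp[:, j * dilation : j * dilation + L]
        return S.reshape(KERNEL_LENGTH, N * L)

    # -- fitting -----------------------------------------------------------

    def fit(self, X: np.ndarray) -> "MiniRocketTransform":
        """Fix dilations, channel combinations and PPV biases from training
        windows. X: (N, L, C)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValidationError("expected (N, L, C) window array")
        N, L, C = X.shape
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.n_time, self.n_channels = L, C
        self.weights = kernel_weight_matrix()
        self.dilations, self.features_per_dilation = fit_dilations(
            L, cfg.feature_budget, cfg.max_dilations_per_kernel
        )
        sub = X
        if N > cfg.bias_sample_size:
            sub = X[rng.choice(N, cfg.bias_sample_size, replace=False)]
        Ns = sub.shape[0]
        max_pow = int(np.floor(np.log2(C))) if C > 1 else 0
        groups = self._groups()
        self.channel_sets: dict[tuple[int, int], np.ndarray] = {}
        self.biases: dict[tuple[int, int], np.ndarray] = {}  # (kernel, di) -> biases
        for di, dilation in enumerate(self.dilations):
            m = int(self.features_per_dilation[di])
            qs = (np.arange(m) + 1.0) / (m + 1.0)
            for g, rows in enumerate(groups):
                n_comb = 2 ** int(rng.integers(0, max_pow + 1))
                chans = np.sort(rng.choice(C, size=min(n_comb, C), replace=False))
                self.channel_sets[(di, g)] = chans
                S = self._shifted_stack(sub, int(dilation), chans)
                conv = (self.weights[rows] @ S).reshape(len(rows), Ns, L)
                for j, ki in enumerate(rows):
                    self.biases[(int(ki), di)] = np.quantile(conv[j], qs)
        self._n_features = int(self.features_per_dilation.sum()) * N_KERNELS
        self._fitted = True
        return self

    # -- transform ---------------------------------------------------------

    def transform(self, X: np.ndarray, chunk: int = 2048) -> np.ndarray:
        """(N, L, C) windows -> (N, n_features) PPV feature matrix in [0, 1]."""
        if not self._fitted:
            raise ValidationError("transform must be fitted before use")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != self.n_time or X.shape[2] != self.n_channels:
            raise ValidationError(
                f"expected windows of shape (N, {self.n_time}, {self.n_channels}), "
                f"got {X.shape}"
            )
        N, L = X.shape[0], self.n_time
        out = np.empty((N, self._n_features), dtype=np.float32)
        groups = self._groups()
        for lo in range(0, N, chunk):
            Xb = X[lo : lo + chunk]
            Nb = Xb.shape[0]
            for di, dilation in enumerate(self.dilations):
                m = int(self.features_per_dilation[di])
                for g, rows in enumerate(groups):
                    S = self._shifted_stack(Xb, int(dilation), self.channel_sets[(di, g)])
                    conv = (self.weights[rows] @ S).reshape(len(rows), Nb, L)
                    for j, ki in enumerate(rows):
                        col = self._column(int(ki), di)
                        b = self.biases[(int(ki), di)]
                        out[lo : lo + Nb, col : col + m] = (
                            conv[j][:, None, :] > b[None, :, None]
                        ).mean(axis=2)
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


class MiniRocketModel(FittedModel):
    family = "minirocket"

    def __init__(self, config: MiniRocketConfig, channel_names: tuple[str, ...]):
        super().__init__(channel_names)
        self.config = config
        self.transformer = MiniRocketTransform(config)
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MiniRocketModel":
        cfg = self.config
        F = self.transformer.fit_transform(X)
        self._mu = F.mean(axis=0)
        sd = F.std(axis=0)
        self._sd = np.where(sd < 1e-8, 1.0, sd)
        Fs = ((F - self._mu) / self._sd).astype(np.float32)
        w = sample_weights(y)
        p_coef = _nn.Param(np.zeros(F.shape[1], dtype=np.float32))
        p_bias = _nn.Param(np.zeros(1, dtype=np.float32))
        opt = _nn.AdamW([p_coef, p_bias], lr=cfg.head_learning_rate)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0]
        )
        for _ in range(cfg.head_epochs):
            for idx in _nn.minibatches(len(y), cfg.head_batch_size, rng):
                opt.zero_grad()
                z = Fs[idx] @ p_coef.value + p_bias.value[0]
                _, dz = _nn.weighted_bce_with_logits(z, y[idx], w[idx])
                p_coef.grad += Fs[idx].T @ dz
                p_bias.grad += dz.sum(keepdims=True)
                opt.step()
        self.coef_ = p_coef.value.astype(np.float64)
        self.intercept_ = float(p_bias.value[0])
        return self

    def predict_proba(
        self, X: np.ndarray, channel_names: tuple[str, ...] | None = None
    ) -> np.ndarray:
        self.check_channels(X, channel_names)
        if self.coef_ is None:
            raise ValidationError("model has not been fitted")
        F = self.transformer.transform(X)
        Fs = (F - self._mu) / self._sd
        return _nn.sigmoid(Fs @ self.coef_ + self.intercept_)


def train_minirocket(
    train: WindowDataset, config: MiniRocketConfig | None = None
) -> MiniRocketModel:
    config = config or MiniRocketConfig()
    X, y = training_arrays(train)
    model = MiniRocketModel(config, train.channel_names)
    return model.fit(X, y)
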