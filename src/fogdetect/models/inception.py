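"""InceptionTime-style ensemble for window classification.

Each network stacks ``depth`` inception modules: a 1x1 bottleneck feeding
three parallel convolutions (kernel sizes 2, 4 and 8 — reduced from the
reference 10/20/40 to curb parameters on 2-s windows), plus a stride-1
max-pool branch through a 1x1 convolution; branch outputs are concatenated,
batch-normalized and passed through ReLU, with a residual shortcut added
every third module. A global-average-pool head feeds one logit. The ensemble
averages the sigmoid outputs of ``n_ensemble`` independently initialized
networks trained on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..windowing import WindowDataset
from . import _nn
from .base import FittedModel, sample_weights, training_arrays


@dataclass
class InceptionConfig:
    n_ensemble: int = 5
    kernel_sizes: tuple[int, int, int] = (2, 4, 8)
    depth: int = 6
    bottleneck: int = 32
    filters: int = 32  # per branch
    residual_every: int = 3
    epochs: int = 20
    learning_rate: float = 0.001
    batch_size: int = 64
    weight_decay: float = 0.0
    seed: int = 0


class _InceptionModule:
    def __init__(self, in_ch: int, cfg: InceptionConfig, rng: np.random.Generator):
        self.bottleneck = _nn.Conv1d(in_ch, cfg.bottleneck, 1, rng, bias=False)
        self.convs = [
            _nn.Conv1d(cfg.bottleneck, cfg.filters, k, rng, bias=False)
            for k in cfg.kernel_sizes
        ]
        self.mp = _nn.MaxPoolSame(3)
        self.mp_conv = _nn.Conv1d(in_ch, cfg.filters, 1, rng, bias=False)
        self.out_ch = cfg.filters * (len(cfg.kernel_sizes) + 1)
        self.bn = _nn.BatchNorm1d(self.out_ch)
        self.relu = _nn.ReLU()

    def params(self) -> list[_nn.Param]:
        out = self.bottleneck.params() + self.mp_conv.params() + self.bn.params()
        for c in self.convs:
            out.extend(c.params())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b = self.bottleneck.forward(x, train)
        branches = [c.forward(b, train) for c in self.convs]
        branches.append(self.mp_conv.forward(self.mp.forward(x, train), train))
        z = np.concatenate(branches, axis=1)
        return self.relu.forward(self.bn.forward(z, train), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.bn.backward(self.relu.backward(grad))
        f = self.convs[0].out_ch
        db = None
        for i, c in enumerate(self.convs):
            g = c.backward(grad[:, i * f : (i + 1) * f])
            db = g if db is None else db + g
        g_mp = self.mp.backward(self.mp_conv.backward(grad[:, len(self.convs) * f :]))
        dx = self.bottleneck.backward(db)
        return dx + g_mp


class _Shortcut:
    """1x1 conv + BN residual projection."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv = _nn.Conv1d(in_ch, out_ch, 1, rng, bias=False)
        self.bn = _nn.BatchNorm1d(out_ch)

    def params(self) -> list[_nn.Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.bn.forward(self.conv.forward(x, train), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(grad))


class _InceptionNet:
    def __init__(self, in_ch: int, cfg: InceptionConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.modules: list[_InceptionModule] = []
        self.shortcuts: dict[int, _Shortcut] = {}
        self.res_relus: dict[int, _nn.ReLU] = {}
        ch = in_ch
        res_ch = in_ch
        for d in range(cfg.depth):
            mod = _InceptionModule(ch, cfg, rng)
            self.modules.append(mod)
            ch = mod.out_ch
            if (d + 1) % cfg.residual_every == 0:
                self.shortcuts[d] = _Shortcut(res_ch, ch, rng)
                self.res_relus[d] = _nn.ReLU()
                res_ch = ch
        self.gap = _nn.GlobalAvgPool()
        self.head = _nn.Dense(ch, 1, rng)

    def params(self) -> list[_nn.Param]:
        out: list[_nn.Param] = []
        for m in self.modules:
            out.extend(m.params())
        for s in self.shortcuts.values():
            out.extend(s.params())
        out.extend(self.gap.params())
        out.extend(self.head.params())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        res_input = x
        for d, mod in enumerate(self.modules):
            x = mod.forward(x, train)
            if d in self.shortcuts:
                x = x + self.shortcuts[d].forward(res_input, train)
                x = self.res_relus[d].forward(x, train)
                res_input = x
        pooled = self.gap.forward(x, train)
        return self.head.forward(pooled, train)[:, 0]

    def backward(self, dz: np.ndarray) -> None:
        grad = self.gap.backward(self.head.backward(dz[:, None]))
        # residual gradients re-entering at the input of a given module index
        pending: dict[int, np.ndarray] = {}
        for d in reversed(range(len(self.modules))):
            if d in self.shortcuts:
                grad = self.res_relus[d].backward(grad)
                g_res = self.shortcuts[d].backward(grad)
                src = self._res_source(d)
                # the shortcut source is the output of module `src` (post-join),
                # i.e. the input of module `src + 1`; src == -1 is the net input
                key = src + 1
                pending[key] = pending[key] + g_res if key in pending else g_res
            grad = self.modules[d].backward(grad)
            if d in pending:  # grad is now w.r.t. the input of module d
                grad = grad + pending.pop(d)

    def _res_source(self, join: int) -> int:
        """Module index whose *output* feeds shortcut `join` (-1 = input)."""
        prev = [j for j in self.shortcuts if j < join]
        return max(prev) if prev else -1


class InceptionTimeModel(FittedModel):
    family = "inceptiontime"

    def __init__(self, config: InceptionConfig, channel_names: tuple[str, ...]):
        super().__init__(channel_names)
        self.config = config
        self.nets: list[_InceptionNet] = []
        in_ch = len(channel_names)
        for i in range(config.n_ensemble):
            init_seed = np.random.SeedSequence([config.seed, 10 + i]).generate_state(1)[0]
            self.nets.append(
                _InceptionNet(in_ch, config, np.random.default_rng(init_seed))
            )

    def n_parameters(self) -> int:
        return sum(p.value.size for net in self.nets for p in net.params())

    def fit(self, X: np.ndarray, y: np.ndarray) -> "InceptionTimeModel":
        cfg = self.config
        w = sample_weights(y).astype(np.float32)
        Xc = np.ascontiguousarray(X.transpose(0, 2, 1), dtype=np.float32)
        for i, net in enumerate(self.nets):
            opt = _nn.AdamW(net.params(), lr=cfg.learning_rate,
                            weight_decay=cfg.weight_decay)
            shuffle_rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 100 + i]).generate_state(1)[0]
            )
            for _ in range(cfg.epochs):
                for idx in _nn.minibatches(len(y), cfg.batch_size, shuffle_rng):
                    opt.zero_grad()
                    z = net.forward(Xc[idx], train=True)
                    _, dz = _nn.weighted_bce_with_logits(z, y[idx], w[idx])
                    net.backward(dz)
                    opt.step()
        return self

    def member_probabilities(self, X: np.ndarray) -> np.ndarray:
        """(n_ensemble, N) matrix of per-network sigmoid outputs."""
        Xc = np.ascontiguousarray(X.transpose(0, 2, 1), dtype=np.float32)
        out = np.empty((len(self.nets), len(Xc)))
        for j, net in enumerate(self.nets):
            for i in range(0, len(Xc), 1024):
                z = net.forward(Xc[i : i + 1024], train=False)
                out[j, i : i + 1024] = _nn.sigmoid(z)
        return out

    def predict_proba(
        self, X: np.ndarray, channel_names: tuple[str, ...] | None = None
    ) -> np.ndarray:
        self.check_channels(X, channel_names)
        return self.member_probabilities(X).mean(axis=0)


def train_inceptiontime(
    train: WindowDataset, config: InceptionConfig | None = None
) -> InceptionTimeModel:
    config = config or InceptionConfig()
    X, y = training_arrays(train)
    model = InceptionTimeModel(config, train.channel_names)
    return model.fit(X, y)
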