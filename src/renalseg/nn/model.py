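"""FR2PAttU-Net: a U-shaped segmentation network whose double-conv blocks
are replaced by recurrent-residual *parallel* convolution (R2P) blocks and
whose skip connections pass through attention gates.

An R2P block runs one branch per kernel size (e.g. 3x3 and 5x5) on the same
input; each branch is two stacked recurrent convolution units; branch
outputs are concatenated channel-wise, projected back to ``out_channels``
with a 1x1 convolution (when there is more than one branch), and a
1x1-projected copy of the block input is added as a residual.

A recurrent convolution unit computes ``z = conv(x)`` followed by ``t``
accumulation steps ``h <- act(norm(conv_r(h) + z))`` with the step
convolution's weights shared across steps; ``t = 0`` reduces the unit to a
plain conv-norm-activation layer.

The attention gate receives the skip feature ``x`` and the one-level-coarser
decoder signal ``g``: ``g`` is upsampled and convolved onto ``x``'s grid,
both are 1x1-projected to half of ``x``'s channels, summed, passed through
Leaky-ReLU, reduced to one channel, and squashed by the logistic function
into an attention map in (0, 1) that multiplies ``x`` element-wise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..errors import ConfigurationError
from .autodiff import (Tensor, as_tensor, concat, leaky_relu, maxpool2x2,
                       sigmoid, softmax, upsample2x)
from .layers import BatchNorm2d, Conv2d, Dropout, Module

__all__ = [
    "R2PBlockConfig", "NetworkConfig", "RecurrentConvUnit", "R2PBlock",
    "AttentionGate", "FR2PAttUNet", "build_network", "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class R2PBlockConfig:
    """Hyper-parameters shared by every R2P block of a network."""

    kernel_sizes: tuple[int, ...] = (3,)
    recurrence_steps: int = 2
    leaky_slope: float = 0.01
    use_batchnorm: bool = True
    dropout_rate: float = 0.2

    def __post_init__(self):
        if len(self.kernel_sizes) == 0:
            raise ConfigurationError("kernel_sizes must be non-empty")
        if any(k % 2 == 0 or k < 1 for k in self.kernel_sizes):
            raise ConfigurationError("kernel sizes must be odd positive ints")
        if self.recurrence_steps < 0:
            raise ConfigurationError("recurrence_steps must be >= 0")
        if not (0.0 < self.leaky_slope < 1.0):
            raise ConfigurationError("leaky_slope must be in (0, 1)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of one U-shaped model."""

    input_size: int = 128
    depth: int = 4
    base_filters: int = 32
    n_classes: int = 2
    block: R2PBlockConfig = field(default_factory=R2PBlockConfig)

    def __post_init__(self):
        if self.depth < 1 or self.base_filters < 1:
            raise ConfigurationError("depth and base_filters must be >= 1")
        if self.n_classes not in (2, 3):
            raise ConfigurationError("n_classes must be 2 (coarse) or 3 (fine)")
        if self.input_size % (2 ** self.depth) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by 2^{self.depth}"
            )

    @property
    def bottleneck_side(self) -> int:
        """Spatial side of the deepest feature map ('last layer image size')."""
        return self.input_size // (2 ** self.depth)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block"]["kernel_sizes"] = list(self.block.kernel_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        b = dict(d["block"])
        b["kernel_sizes"] = tuple(b["kernel_sizes"])
        return cls(**{**d, "block": R2PBlockConfig(**b)})


class _Norm(Module):
    """BatchNorm2d or identity, per block config."""

    def __init__(self, channels: int, use_batchnorm: bool):
        super().__init__()
        self.bn = BatchNorm2d(channels) if use_batchnorm else None

    def __call__(self, x):
        return self.bn(x) if self.bn is not None else as_tensor(x)


class RecurrentConvUnit(Module):
    def __init__(self, in_channels, out_channels, kernel_size, cfg, rng):
        super().__init__()
        self.t = cfg.recurrence_steps
        self.slope = cfg.leaky_slope
        self.conv_in = Conv2d(in_channels, out_channels, kernel_size, rng)
        self.norm_in = _Norm(out_channels, cfg.use_batchnorm)
        if self.t > 0:
            self.conv_rec = Conv2d(out_channels, out_channels, kernel_size, rng)
            self.norm_rec = _Norm(out_channels, cfg.use_batchnorm)

    def __call__(self, x):
        z = self.conv_in(x)
        h = leaky_relu(self.norm_in(z), self.slope)
        for _ in range(self.t):
            h = leaky_relu(self.norm_rec(self.conv_rec(h) + z), self.slope)
        return h


class R2PBranch(Module):
    """Two stacked recurrent conv units with one kernel size."""

    def __init__(self, in_channels, out_channels, kernel_size, cfg, rng):
        super().__init__()
        self.unit1 = RecurrentConvUnit(in_channels, out_channels, kernel_size,
                                       cfg, rng)
        self.unit2 = RecurrentConvUnit(out_channels, out_channels, kernel_size,
                                       cfg, rng)

    def __call__(self, x):
        return self.unit2(self.unit1(x))


class R2PBlock(Module):
    def __init__(self, in_channels: int, out_channels: int,
                 cfg: R2PBlockConfig, rng: np.random.Generator):
        super().__init__()
        self.branches = [
            R2PBranch(in_channels, out_channels, k, cfg, rng)
            for k in cfg.kernel_sizes
        ]
        self.project = (
            Conv2d(out_channels * len(self.branches), out_channels, 1, rng)
            if len(self.branches) > 1 else None
        )
        self.residual = Conv2d(in_channels, out_channels, 1, rng)

    def __call__(self, x):
        x = as_tensor(x)
        outs = [branch(x) for branch in self.branches]
        y = outs[0] if self.project is None else self.project(concat(outs, 1))
        return y + self.residual(x)


class AttentionGate(Module):
    """Gates the skip feature x by a map computed from x and the coarser g."""

    def __init__(self, x_channels: int, g_channels: int, slope: float,
                 rng: np.random.Generator):
        super().__init__()
        inter = max(x_channels // 2, 1)
        self.slope = slope
        self.up_conv = Conv2d(g_channels, g_channels, 3, rng)
        self.theta_x = Conv2d(x_channels, inter, 1, rng)
        self.phi_g = Conv2d(g_channels, inter, 1, rng)
        self.psi = Conv2d(inter, 1, rng=rng, kernel_size=1)

    def attention_map(self, x, g) -> Tensor:
        x, g = as_tensor(x), as_tensor(g)
        if g.shape[2] * 2 == x.shape[2]:
            g = upsample2x(g)
        elif g.shape[2] != x.shape[2]:
            raise ValueError(
                f"gating signal side {g.shape[2]} is neither equal to nor half "
                f"of skip side {x.shape[2]}"
            )
        g = self.up_conv(g)
        a = leaky_relu(self.theta_x(x) + self.phi_g(g), self.slope)
        return sigmoid(self.psi(a))

    def __call__(self, x, g):
        return as_tensor(x) * self.attention_map(x, g)


class FR2PAttUNet(Module):
    """Encoder-decoder with R2P blocks and attention-gated skips."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        b = cfg.block
        chans = [cfg.base_filters * 2 ** i for i in range(cfg.depth + 1)]

        self.encoders = []
        c_in = 1
        for c in chans[:-1]:
            self.encoders.append(R2PBlock(c_in, c, b, rng))
            c_in = c
        self.bottleneck = R2PBlock(chans[-2], chans[-1], b, rng)
        self.bottleneck_dropout = Dropout(
            b.dropout_rate, np.random.default_rng(rng.integers(2**31)))

        self.up_convs, self.gates, self.decoders = [], [], []
        for level in reversed(range(cfg.depth)):
            c_skip, c_deep = chans[level], chans[level + 1]
            self.up_convs.append(Conv2d(c_deep, c_skip, 3, rng))
            self.gates.append(AttentionGate(c_skip, c_deep, b.leaky_slope, rng))
            self.decoders.append(R2PBlock(2 * c_skip, c_skip, b, rng))
        self.head = Conv2d(chans[0], cfg.n_classes, 1, rng)

    def __call__(self, x) -> Tensor:
        """Forward pass to per-pixel class logits (N, n_classes, H, W)."""
        x = as_tensor(x)
        if x.ndim != 4 or x.shape[2] != self.cfg.input_size \
                or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected (N, 1, {self.cfg.input_size}, {self.cfg.input_size}),"
                f" got {x.shape}"
            )
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
            h = maxpool2x2(h)
        h = self.bottleneck_dropout(self.bottleneck(h))
        for up, gate, dec, skip in zip(self.up_convs, self.gates,
                                       self.decoders, reversed(skips)):
            gated = gate(skip, h)  # g is one level coarser than the skip
            h = up(upsample2x(h))
            h = dec(concat([gated, h], axis=1))
        return self.head(h)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities for an (N, 1, H, W) batch."""
        was_training = self.training
        self.eval()
        try:
            probs = softmax(self(Tensor(batch)), axis=1).data
        finally:
            self.train(was_training)
        return probs


def build_network(cfg: NetworkConfig, seed: int = 0) -> FR2PAttUNet:
    """Construct a model from its configuration (deterministic given seed)."""
    return FR2PAttUNet(cfg, seed=seed)


def save_checkpoint(path, model: FR2PAttUNet, extra: dict | None = None):
    """Serialize parameters, buffers and the embedded config to one file."""
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    np.savez(Path(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> FR2PAttUNet:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    cfg = NetworkConfig.from_dict(meta["config"])
    model = FR2PAttUNet(cfg)
    model.load_state_arrays(arrays)
    return model
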