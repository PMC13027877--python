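"""Shared parameterized operators composed by every other module.

Three blocks recur throughout the network:

* ``CGR``  -- 3x3 convolution, group normalisation, ReLU.
* ``BGR``  -- bottleneck convolution (1x1 reduce, 3x3 core, 1x1 expand),
  group normalisation, ReLU.
* ``ChannelAttentionSE`` -- squeeze-and-excitation channel recalibration:
  global average pool, two 1x1 projections with a ReLU between, sigmoid
  gate multiplied back onto the input.

All blocks preserve batch and spatial extents; CGR/BGR outputs are
elementwise nonnegative (ReLU last); the SE gate lies strictly in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .exceptions import ConfigurationError
from .nn import ops

__all__ = ["BlockConfig", "CGR", "BGR", "ChannelAttentionSE", "fitting_reduction"]


@dataclass(frozen=True)
class BlockConfig:
    """Hyperparameters shared by the three building blocks."""

    channels_in: int
    channels_out: int
    bottleneck_ratio: int = 4
    gn_groups: int = 8
    ca_reduction: int = 16

    def __post_init__(self):
        if self.channels_in < 1 or self.channels_out < 1:
            raise ConfigurationError("channel counts must be positive")
        if self.bottleneck_ratio < 1:
            raise ConfigurationError("bottleneck_ratio must be a positive integer")
        if self.bottleneck_ratio > self.channels_in:
            raise ConfigurationError(
                f"bottleneck_ratio {self.bottleneck_ratio} exceeds "
                f"channels_in {self.channels_in}"
            )
        if self.gn_groups < 1 or self.ca_reduction < 1:
            raise ConfigurationError("gn_groups and ca_reduction must be >= 1")


class CGR(nn.Module):
    """3x3 conv -> GroupNorm -> ReLU, shape preserving."""

    def __init__(self, cfg: BlockConfig):
        super().__init__()
        self.cfg = cfg
        self.conv = nn.Conv2d(cfg.channels_in, cfg.channels_out, 3, padding=1)
        self.norm = nn.GroupNorm(cfg.gn_groups, cfg.channels_out)

    def forward(self, x):
        if x.shape[1] != self.cfg.channels_in:
            raise ConfigurationError(
                f"CGR expects {self.cfg.channels_in} channels, got {x.shape[1]}"
            )
        return ops.relu(self.norm(self.conv(x)))


class BGR(nn.Module):
    """Bottleneck conv (1x1 reduce / 3x3 / 1x1 expand) -> GroupNorm -> ReLU.

    The internal width is ``channels_in // bottleneck_ratio`` (at least 1).
    """

    def __init__(self, cfg: BlockConfig):
        super().__init__()
        self.cfg = cfg
        hidden = max(1, cfg.channels_in // cfg.bottleneck_ratio)
        self.hidden = hidden
        self.reduce = nn.Conv2d(cfg.channels_in, hidden, 1)
        self.core = nn.Conv2d(hidden, hidden, 3, padding=1)
        self.expand = nn.Conv2d(hidden, cfg.channels_out, 1)
        self.norm = nn.GroupNorm(cfg.gn_groups, cfg.channels_out)

    def forward(self, x):
        if x.shape[1] != self.cfg.channels_in:
            raise ConfigurationError(
                f"BGR expects {self.cfg.channels_in} channels, got {x.shape[1]}"
            )
        h = self.expand(self.core(self.reduce(x)))
        return ops.relu(self.norm(h))


class ChannelAttentionSE(nn.Module):
    """Squeeze-and-excitation: rescale each channel by a sigmoid weight
    derived from its global average."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels % _clamped(reduction, channels) != 0:
            raise ConfigurationError(
                f"ca_reduction {reduction} does not divide {channels} channels"
            )
        self.channels = channels
        self.reduction = _clamped(reduction, channels)
        hidden = channels // self.reduction
        self.squeeze = nn.Conv2d(channels, hidden, 1)
        # small positive bias keeps the squeeze units initially active
        self.squeeze.bias.data[:] = 0.1
        self.excite = nn.Conv2d(hidden, channels, 1)

    @classmethod
    def from_config(cls, cfg: BlockConfig) -> "ChannelAttentionSE":
        if cfg.channels_in % _clamped(cfg.ca_reduction, cfg.channels_in) != 0:
            raise ConfigurationError(
                f"ca_reduction {cfg.ca_reduction} does not divide "
                f"{cfg.channels_in} channels"
            )
        return cls(cfg.channels_in, cfg.ca_reduction)

    def gate(self, x):
        """Per-channel sigmoid weights of shape (B, C, 1, 1), each in (0, 1)."""
        pooled = ops.mean(x, axis=(2, 3), keepdims=True)
        return ops.sigmoid(self.excite(ops.relu(self.squeeze(pooled))))

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"channel attention expects {self.channels} channels, got {x.shape[1]}"
            )
        return ops.mul(x, self.gate(x))


def _clamped(reduction: int, channels: int) -> int:
    """Clamp the squeeze ratio so the hidden width stays >= 1."""
    return max(1, min(reduction, channels))


def fitting_reduction(channels: int, requested: int = 16) -> int:
    """Largest divisor of ``channels`` not exceeding ``requested``.

    Higher-level modules use this to instantiate channel attention for
    arbitrary channel counts without tripping the divisibility contract.
    The ratio is additionally capped so the squeezed width stays >= 2
    (a single hidden unit behind a ReLU is one dead neuron from inert).
    """
    r = _clamped(min(requested, max(1, channels // 2)), channels)
    while channels % r:
        r -= 1
    return r
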