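"""Hierarchical five-level encoder with foreground-background attention.

The backbone is a configurable stage-wise convolutional extractor (strided
stem to 1/4 resolution, then four stride-2 stages, each optionally followed
by a residual selective-scan block) exposing the five-level contract:
level i of an (H, W) input has extents (H / 2^(i+1), W / 2^(i+1)).

Foreground-background attention applies channel attention, then spatial
attention, and adds the input back: ``out = SA(CA(f)) + f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import nn
from .asm import SS2D, SS2DParams
from .blocks import CGR, BlockConfig, ChannelAttentionSE, fitting_reduction
from .exceptions import ConfigurationError, InputError
from .nn import ops
from .types import FeaturePyramid

__all__ = ["EncoderConfig", "FBA", "Encoder", "extract_pyramid"]

STEM_STRIDE = 4
PYRAMID_STRIDES = (4, 8, 16, 32, 64)


@dataclass(frozen=True)
class EncoderConfig:
    channels: tuple[int, ...] = (16, 32, 64, 96, 128)
    use_ssm_stages: tuple[bool, ...] = (False, False, False, True, True)
    fba_enabled: bool = True
    in_channels: int = 3
    state_dim: int = 16
    gn_groups: int = 8

    def __post_init__(self):
        if len(self.channels) != 5 or len(self.use_ssm_stages) != 5:
            raise ConfigurationError("encoder needs 5 channel counts and 5 SSM flags")
        if any(c < 1 for c in self.channels):
            raise ConfigurationError("channel counts must be positive")
        if any(b > a for a, b in zip(self.channels[1:], self.channels)):
            raise ConfigurationError("channel counts must be nondecreasing")


class SpatialAttention(nn.Module):
    """Gate from channel-pooled max+mean maps through a 7x7 conv + sigmoid."""

    def __init__(self):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, 7, padding=3)

    def gate(self, x):
        pooled = ops.concatenate(
            [ops.mean(x, axis=1, keepdims=True), ops.max(x, axis=1, keepdims=True)],
            axis=1,
        )
        return ops.sigmoid(self.conv(pooled))

    def forward(self, x):
        return ops.mul(x, self.gate(x))


class FBA(nn.Module):
    """Foreground-background attention: sequential channel then spatial
    reweighting with a residual shortcut.  Never changes extents."""

    def __init__(self, channels: int, ca_reduction: int | None = None):
        super().__init__()
        red = ca_reduction if ca_reduction is not None else fitting_reduction(channels)
        self.ca = ChannelAttentionSE(channels, red)
        self.sa = SpatialAttention()

    def forward(self, x):
        return ops.add(self.sa(self.ca(x)), x)


class _Stage(nn.Module):
    """One stride-2 encoder stage: downsampling conv + CGR refinement,
    optionally followed by a residual selective-scan block."""

    def __init__(self, c_in: int, c_out: int, use_ssm: bool, cfg: EncoderConfig):
        super().__init__()
        self.down = nn.Conv2d(c_in, c_out, 3, stride=2, padding=1)
        self.norm = nn.GroupNorm(cfg.gn_groups, c_out)
        self.refine = CGR(BlockConfig(c_out, c_out, gn_groups=cfg.gn_groups))
        self.ssm = SS2D(c_out, SS2DParams(cfg.state_dim)) if use_ssm else None

    def forward(self, x):
        x = self.refine(ops.relu(self.norm(self.down(x))))
        if self.ssm is not None:
            x = ops.add(self.ssm(x), x)
        return x


class Encoder(nn.Module):
    """Five-level pyramid extractor with per-level FBA."""

    def __init__(self, cfg: EncoderConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or EncoderConfig()
        c = cfg.channels
        # stem: two stride-2 convs -> level 1 at stride 4
        self.stem_a = nn.Conv2d(cfg.in_channels, c[0], 3, stride=2, padding=1)
        self.stem_norm = nn.GroupNorm(cfg.gn_groups, c[0])
        self.stem_b = nn.Conv2d(c[0], c[0], 3, stride=2, padding=1)
        self.stage1 = CGR(BlockConfig(c[0], c[0], gn_groups=cfg.gn_groups))
        self.ssm1 = SS2D(c[0], SS2DParams(cfg.state_dim)) if cfg.use_ssm_stages[0] else None
        for i in range(1, 5):
            setattr(self, f"stage{i + 1}", _Stage(c[i - 1], c[i], cfg.use_ssm_stages[i], cfg))
        for i in range(5):
            setattr(self, f"fba{i + 1}", FBA(c[i]) if cfg.fba_enabled else nn.Identity())

    def forward(self, images) -> FeaturePyramid:
        B, C, H, W = images.shape
        if H % 64 or W % 64:
            raise InputError(
                f"input extents must be divisible by 64 (five halvings after a "
                f"stride-{STEM_STRIDE} stem); got {(H, W)}"
            )
        x = self.stage1(self.stem_b(ops.relu(self.stem_norm(self.stem_a(images)))))
        if self.ssm1 is not None:
            x = ops.add(self.ssm1(x), x)
        levels = [x]
        for i in range(2, 6):
            x = getattr(self, f"stage{i}")(x)
            levels.append(x)
        attended = [getattr(self, f"fba{i + 1}")(lvl) for i, lvl in enumerate(levels)]
        return FeaturePyramid(attended)


def extract_pyramid(images, cfg: EncoderConfig | None = None) -> FeaturePyramid:
    """Convenience one-shot pyramid extraction with a fresh encoder."""
    return Encoder(cfg)(images)
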