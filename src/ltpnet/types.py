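"""Lightweight validated containers for features flowing through the net.

The neural modules themselves exchange raw :class:`~ltpnet.nn.Tensor`
objects; :class:`FeatureMap` / :class:`FeaturePyramid` are the validated
views used at module boundaries, in debug assertions, and in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ShapeError
from .nn import Tensor

# Stage provenance tags for intermediate features.  Every intermediate of
# the dataflow carries one of these roles.
FEATURE_ROLES = frozenset(
    {
        "backbone",          # raw pyramid level
        "attended",          # after foreground-background attention
        "spatial_stage1",    # first DB/FFN residual stage
        "spatial_core",      # parallel gated-attention + selective-scan core
        "spatial_stage2",    # second DB/FFN residual stage
        "spatial_refined",   # spatial-modulator output (upsampled)
        "channel_refined",   # lite-gate attention output
        "gate",              # multiplicative spatial gate
        "gated",             # channel-recalibrated gate
        "fused",             # triple-path fusion output
        "common",            # additive fusion path
        "saliency",          # multiplicative fusion path
        "difference",        # subtractive fusion path
        "probability",       # head output
    }
)


@dataclass
class FeatureMap:
    """A rank-4 (batch, channels, height, width) feature with a role tag."""

    data: Tensor
    role: str = "backbone"

    def __post_init__(self):
        if not isinstance(self.data, Tensor):
            self.data = Tensor(np.asarray(self.data))
        if self.data.ndim != 4:
            raise ShapeError(f"FeatureMap must be rank 4, got rank {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ShapeError("all FeatureMap extents must be >= 1")
        if not np.all(np.isfinite(self.data.data)):
            raise ShapeError("FeatureMap contains non-finite values")
        if self.role not in FEATURE_ROLES:
            raise ValueError(f"unknown feature role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape


@dataclass
class FeaturePyramid:
    """Five feature levels with strictly halving spatial extents."""

    levels: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.levels) != 5:
            raise ShapeError(f"pyramid must have exactly 5 levels, got {len(self.levels)}")
        for prev, nxt in zip(self.levels, self.levels[1:]):
            ph, pw = _extents(prev)
            nh, nw = _extents(nxt)
            if nh != max(1, ph // 2) or nw != max(1, pw // 2):
                raise ShapeError(
                    f"pyramid levels must halve: {(ph, pw)} -> {(nh, nw)}"
                )

    def __iter__(self):
        return iter(self.levels)

    def __getitem__(self, i):
        return self.levels[i]

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(_shape(l)[1] for l in self.levels)


def _shape(level) -> tuple[int, ...]:
    return level.shape if not isinstance(level, FeatureMap) else level.data.shape


def _extents(level) -> tuple[int, int]:
    s = _shape(level)
    return s[2], s[3]
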