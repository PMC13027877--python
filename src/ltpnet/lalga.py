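"""Lite-gate attention: asymmetric dual-path spatial gating followed by
global-guided channel recalibration, wrapped in a bottleneck residual:

    y = BGR(GGCA(LAGA(x)) + x)

LAGA is structurally asymmetric: the shallow path is a single BGR block,
the deep path cascades two, and the two are multiplied elementwise (the
deep output acting as the gate).  GGCA rescales each channel of the gate
by a sigmoid weight computed from its global average.
"""

from __future__ import annotations

from . import nn
from .blocks import BGR, BlockConfig
from .nn import ops

__all__ = ["LAGA", "GGCA", "LALGA"]


class LAGA(nn.Module):
    """Asymmetric spatial gate: ``fgate = BGR(x) * BGR(BGR(x))``.

    The output is elementwise nonnegative for any parameters (product of
    two ReLU-terminated branches).
    """

    def __init__(self, channels: int, bottleneck_ratio: int = 4, gn_groups: int = 8):
        super().__init__()
        cfg = BlockConfig(channels, channels, bottleneck_ratio=bottleneck_ratio,
                          gn_groups=gn_groups)
        self.shallow = BGR(cfg)
        self.deep = nn.Sequential(BGR(cfg), BGR(cfg))

    def forward(self, x):
        return ops.mul(self.shallow(x), self.deep(x))


class GGCA(nn.Module):
    """Global-guided channel recalibration.

    ``w = sigmoid(conv(relu(conv(GAP(fgate)))))`` with two 1x1 convs and a
    squeeze between them; the output is ``fgate * w`` with ``w`` broadcast
    over space, so the scaling is spatially uniform per channel and every
    weight lies strictly in (0, 1).
    """

    def __init__(self, channels: int, reduction: int = 4):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.squeeze = nn.Conv2d(channels, hidden, 1)
        # small positive bias keeps the squeeze units initially active
        self.squeeze.bias.data[:] = 0.1
        self.excite = nn.Conv2d(hidden, channels, 1)

    def channel_weights(self, fgate):
        pooled = ops.mean(fgate, axis=(2, 3), keepdims=True)
        return ops.sigmoid(self.excite(ops.relu(self.squeeze(pooled))))

    def forward(self, fgate):
        return ops.mul(fgate, self.channel_weights(fgate))


class LALGA(nn.Module):
    """Channel-preserving refinement: ``y = BGR(GGCA(LAGA(x)) + x)``."""

    def __init__(self, channels: int, bottleneck_ratio: int = 4,
                 ggca_reduction: int = 4, gn_groups: int = 8):
        super().__init__()
        self.laga = LAGA(channels, bottleneck_ratio, gn_groups)
        self.ggca = GGCA(channels, ggca_reduction)
        self.out = BGR(BlockConfig(channels, channels, bottleneck_ratio=bottleneck_ratio,
                                   gn_groups=gn_groups))

    def forward(self, x):
        return self.out(ops.add(self.ggca(self.laga(x)), x))
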