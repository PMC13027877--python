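"""The assembled segmentation network.

Dataflow (levels i = 1..5, shallow to deep, with per-level channels
C1..C5 and strides 4..64):

* the encoder produces five attended levels f1'..f5';
* the deepest level is spatially refined: f5_asm = ASM(f5');
* walking up, for i = 4..1:
    skip_i   = LALGA(fi')
    high_i   = LALGA(f_{i+1}_asm)
    fused_i  = TPFF(high_i, skip_i)
    fi_asm   = ASM(fused_i)            # upsamples to level i-1 scale
* the head maps f1_asm (at input/2) through a bilinear 2x upsample, a
  1x1 conv to one channel and a sigmoid, yielding a probability map at
  input resolution.

Per forward pass this invokes ASM 5 times, LALGA 8 times and TPFF
4 times (tracked in ``LTPNet.call_counts``).  Each component can be
ablated independently; disabled components are replaced by extent-
preserving substitutes so the dataflow contract is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .asm import ASM, SS2DParams
from .encoder import Encoder, EncoderConfig
from .exceptions import ConfigurationError, ShapeError
from .lalga import LALGA
from .nn import Tensor, ops
from .tpff import DEFAULT_INIT_COEFFICIENTS, PATHS, TPFF

__all__ = ["ModelConfig", "LTPNet", "TINY_PRESET", "PAPER_PRESET"]


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    state_dim: int = 16
    ffn_expansion: int = 4
    bottleneck_ratio: int = 4
    ggca_reduction: int = 4
    gn_groups: int = 8
    tpff_enabled_paths: tuple[str, ...] = PATHS
    tpff_init_coefficients: tuple[float, float, float] = DEFAULT_INIT_COEFFICIENTS
    use_fba: bool = True
    use_asm: bool = True
    use_lalga: bool = True
    use_tpff: bool = True
    threshold: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("threshold must lie strictly in (0, 1)")


TINY_PRESET = ModelConfig(
    encoder=EncoderConfig(
        channels=(8, 16, 24, 32, 48),
        # stage 4 so the scan sees sequences longer than 1 even at 64x64
        use_ssm_stages=(False, False, False, True, False),
        state_dim=8,
    ),
    state_dim=8,
    ffn_expansion=2,
)

PAPER_PRESET = ModelConfig()


class _PlainUpsample(nn.Module):
    """Ablation stand-in for ASM: bilinear 2x upsample + 1x1 projection."""

    def __init__(self, channels: int, target_channels: int):
        super().__init__()
        self.proj = nn.Conv2d(channels, target_channels, 1)

    def forward(self, x):
        return self.proj(ops.upsample2x_bilinear(x))


class _PlainFusion(nn.Module):
    """Ablation stand-in for TPFF: element-wise addition."""

    def forward(self, f_high, f_low):
        if f_high.shape != f_low.shape:
            raise ShapeError(
                f"fusion inputs must share extents, got {f_high.shape} vs {f_low.shape}"
            )
        return ops.add(f_high, f_low)


class LTPNet(nn.Module):
    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or ModelConfig()
        enc_cfg = replace(cfg.encoder, fba_enabled=cfg.encoder.fba_enabled and cfg.use_fba)
        self.encoder = Encoder(enc_cfg)
        c = enc_cfg.channels
        ss = SS2DParams(cfg.state_dim)

        def make_asm(c_in, c_out):
            if cfg.use_asm:
                return ASM(c_in, c_out, ss, cfg.ffn_expansion, cfg.gn_groups)
            return _PlainUpsample(c_in, c_out)

        def make_lalga(ch):
            if cfg.use_lalga:
                return LALGA(ch, cfg.bottleneck_ratio, cfg.ggca_reduction, cfg.gn_groups)
            return nn.Identity()

        # ASM at level i consumes level-i channels and emits level-(i-1)
        # channels (level 1 keeps its own channel count for the head).
        targets = {5: c[3], 4: c[2], 3: c[1], 2: c[0], 1: c[0]}
        for i in range(1, 6):
            setattr(self, f"asm{i}", make_asm(c[i - 1], targets[i]))
        for i in range(2, 6):
            setattr(self, f"lalga_deep{i}", make_lalga(targets[i]))
        for i in range(1, 5):
            setattr(self, f"lalga_skip{i}", make_lalga(c[i - 1]))
        for i in range(1, 5):
            if cfg.use_tpff:
                setattr(self, f"tpff{i}", TPFF(
                    c[i - 1], cfg.bottleneck_ratio, cfg.gn_groups,
                    enabled_paths=cfg.tpff_enabled_paths,
                    init_coefficients=cfg.tpff_init_coefficients,
                ))
            else:
                setattr(self, f"tpff{i}", _PlainFusion())
        self.head_conv = nn.Conv2d(c[0], 1, 1)
        # residual chains inflate feature magnitude; damp the head so the
        # initial probabilities stay away from sigmoid saturation
        self.head_conv.weight.data *= 0.05
        self.call_counts: dict[str, int] = {}

    # -- bookkeeping ---------------------------------------------------

    def _count(self, name: str) -> None:
        self.call_counts[name] = self.call_counts.get(name, 0) + 1

    def fusion_modules(self) -> list:
        return [getattr(self, f"tpff{i}") for i in range(1, 5)]

    def assert_simplex(self, tol: float = 1e-9) -> None:
        """Verify every fusion module's coefficients sum to one."""
        for m in self.fusion_modules():
            if isinstance(m, TPFF):
                w = m.coefficients().as_array()
                if abs(w.sum() - 1.0) > tol or np.any(w < 0):
                    raise AssertionError(f"simplex invariant violated: {w}")

    # -- forward -------------------------------------------------------

    def forward(self, images, debug: bool = False):
        self.call_counts = {}
        pyramid = self.encoder(images)
        f = list(pyramid)

        self._count("asm")
        deep = getattr(self, "asm5")(f[4])
        for i in range(4, 0, -1):
            self._count("lalga")
            high = getattr(self, f"lalga_deep{i + 1}")(deep)
            self._count("lalga")
            skip = getattr(self, f"lalga_skip{i}")(f[i - 1])
            if debug and high.shape != skip.shape:
                raise ShapeError(
                    f"fusion junction at level {i}: {high.shape} vs {skip.shape}"
                )
            self._count("tpff")
            fused = getattr(self, f"tpff{i}")(high, skip)
            self._count("asm")
            deep = getattr(self, f"asm{i}")(fused)
        logits = self.head_conv(ops.upsample2x_bilinear(deep))
        return ops.sigmoid(logits)

    def predict(self, images, threshold: float | None = None) -> np.ndarray:
        """Binary masks: probability >= threshold (the documented tie rule)."""
        threshold = self.cfg.threshold if threshold is None else threshold
        if not (0.0 < threshold < 1.0):
            raise ConfigurationError("threshold must lie strictly in (0, 1)")
        probs = self.forward(images)
        return (probs.data >= threshold).astype(np.uint8)
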