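"""Triple-path cross-level fusion.

Both inputs are first passed through bottleneck (BGR) projections, then
combined along three parallel paths:

* common path     ``CP = CA(flow + fhigh) + (flow + fhigh)``
* saliency path   ``SP = CA(flow * fhigh) + flow``
* difference path ``DP = CA(flow - fhigh) + flow``

(the residual asymmetry is deliberate: the common path adds its own sum
back, the other two add the low-level input).  The outputs are blended
with learnable simplex coefficients (alpha, beta, gamma) realised as a
softmax over three logits, initialised to (0.4, 0.2, 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import BGR, BlockConfig, ChannelAttentionSE, fitting_reduction
from .exceptions import ShapeError
from .nn import Tensor, ops

__all__ = ["FusionCoefficients", "normalize_coefficients", "TPFF",
           "DEFAULT_INIT_COEFFICIENTS", "PATHS"]

DEFAULT_INIT_COEFFICIENTS = (0.4, 0.2, 0.4)
PATHS = ("cp", "sp", "dp")


@dataclass(frozen=True)
class FusionCoefficients:
    """Simplex weights for the three fusion paths.

    alpha + beta + gamma == 1 up to machine epsilon and each coefficient
    is strictly positive (softmax of finite logits).
    """

    alpha: float
    beta: float
    gamma: float
    logits: tuple[float, float, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


def normalize_coefficients(logits) -> FusionCoefficients:
    """Map three unconstrained logits onto the open simplex via softmax."""
    arr = np.asarray([float(v) for v in np.ravel(np.asarray(logits, dtype=float))])
    if arr.shape != (3,):
        raise ValueError("expected exactly three logits")
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError("fusion logits must be finite")
    e = np.exp(arr - arr.max())
    w = e / e.sum()
    return FusionCoefficients(float(w[0]), float(w[1]), float(w[2]), tuple(arr))


def _require_same_extents(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise ShapeError(f"{what} inputs must share extents, got {a.shape} vs {b.shape}")


class TPFF(nn.Module):
    """Triple-path fusion of a low-level and a high-level feature.

    ``enabled_paths`` supports the structural ablations (CP only, CP+SP,
    CP+SP+DP); a disabled path's coefficient mass is renormalised over
    the active paths.
    """

    def __init__(self, channels: int, bottleneck_ratio: int = 4, gn_groups: int = 8,
                 ca_reduction: int | None = None,
                 enabled_paths: tuple[str, ...] = PATHS,
                 init_coefficients: tuple[float, float, float] = DEFAULT_INIT_COEFFICIENTS):
        super().__init__()
        unknown = set(enabled_paths) - set(PATHS)
        if unknown:
            raise ValueError(f"unknown fusion paths: {sorted(unknown)}")
        if "cp" not in enabled_paths:
            raise ValueError("the common path cannot be disabled")
        if any(c <= 0 for c in init_coefficients):
            raise ValueError("initial coefficients must be strictly positive")
        self.channels = channels
        self.enabled_paths = tuple(p for p in PATHS if p in enabled_paths)
        cfg = BlockConfig(channels, channels, bottleneck_ratio=bottleneck_ratio,
                          gn_groups=gn_groups)
        self.proj_low = BGR(cfg)
        self.proj_high = BGR(cfg)
        red = ca_reduction if ca_reduction is not None else fitting_reduction(channels)
        self.ca_cp = ChannelAttentionSE(channels, red)
        self.ca_sp = ChannelAttentionSE(channels, red)
        self.ca_dp = ChannelAttentionSE(channels, red)
        self.logits = nn.Parameter(np.log(np.asarray(init_coefficients, dtype=float)))

    # -- coefficients --------------------------------------------------

    def coefficients(self) -> FusionCoefficients:
        """Current simplex weights; disabled paths carry exactly zero mass."""
        full = normalize_coefficients(self.logits.data)
        if len(self.enabled_paths) == 3:
            return full
        w = full.as_array()
        active = np.array([p in self.enabled_paths for p in PATHS])
        w = np.where(active, w, 0.0)
        w = w / w.sum()
        return FusionCoefficients(float(w[0]), float(w[1]), float(w[2]),
                                  tuple(self.logits.data))

    def _coefficient_tensors(self):
        """Differentiable (alpha, beta, gamma): softmax over active logits."""
        active = [PATHS.index(p) for p in self.enabled_paths]
        idx = {a: k for k, a in enumerate(active)}
        sel = np.zeros((len(active), 3))
        for k, a in enumerate(active):
            sel[k, a] = 1.0
        picked = ops.linear(self.logits, Tensor(sel))
        soft = ops.softmax(picked, axis=0)
        out = []
        for i in range(3):
            if i in idx:
                one = np.zeros(len(active))
                one[idx[i]] = 1.0
                out.append(ops.sum(ops.mul(soft, Tensor(one))))
            else:
                out.append(None)
        return out

    # -- the three paths (post-projection inputs) ----------------------

    def common_path(self, flow, fhigh):
        _require_same_extents(flow, fhigh, "common path")
        fcp = ops.add(flow, fhigh)
        return ops.add(self.ca_cp(fcp), fcp)

    def saliency_path(self, flow, fhigh):
        _require_same_extents(flow, fhigh, "saliency path")
        fsp = ops.mul(flow, fhigh)
        return ops.add(self.ca_sp(fsp), flow)

    def difference_path(self, flow, fhigh):
        _require_same_extents(flow, fhigh, "difference path")
        fdp = ops.sub(flow, fhigh)
        return ops.add(self.ca_dp(fdp), flow)

    # -- full fusion ---------------------------------------------------

    def project(self, f_high, f_low):
        """The two input bottleneck projections."""
        return self.proj_low(f_low), self.proj_high(f_high)

    def forward(self, f_high, f_low):
        flow, fhigh = self.project(f_high, f_low)
        _require_same_extents(flow, fhigh, "fusion")
        alpha, beta, gamma = self._coefficient_tensors()
        out = ops.mul(self.common_path(flow, fhigh), alpha)
        if beta is not None:
            out = ops.add(out, ops.mul(self.saliency_path(flow, fhigh), beta))
        if gamma is not None:
            out = ops.add(out, ops.mul(self.difference_path(flow, fhigh), gamma))
        return out
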