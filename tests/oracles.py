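"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written directly against numpy, without touching the
package's autodiff graph, so it stays independent of the code paths it
checks.
"""

from __future__ import annotations

import numpy as np


def softplus(x):
    return np.logaddexp(0.0, x)


def directional_scan_oracle(seq: np.ndarray, scan) -> np.ndarray:
    """Naive per-timestep recurrence for one DirectionalScan module.

    ``seq``: (B, L, C) numpy array.  Replays
    ``h_t = exp(dt_t A) h_{t-1} + dt_t B_t x_t ; y_t = C_t h_t + D x_t``
    one timestep at a time using the module's parameter arrays.
    """
    B, L, C = seq.shape
    A = -np.exp(scan.A_log.data)            # (C, N)
    N = A.shape[1]
    Wd, bd = scan.dt_proj.weight.data, scan.dt_proj.bias.data
    Wb, bb = scan.b_proj.weight.data, scan.b_proj.bias.data
    Wc, bc = scan.c_proj.weight.data, scan.c_proj.bias.data
    D = scan.D.data
    out = np.zeros_like(seq)
    for b in range(B):
        h = np.zeros((C, N))
        for t in range(L):
            x_t = seq[b, t]
            dt = softplus(Wd @ x_t + bd)            # (C,)
            B_t = Wb @ x_t + bb                     # (N,)
            C_t = Wc @ x_t + bc                     # (N,)
            h = np.exp(dt[:, None] * A) * h + (dt * x_t)[:, None] * B_t[None, :]
            out[b, t] = h @ C_t + D * x_t
    return out


def unfold_oracle(x: np.ndarray, direction: int) -> np.ndarray:
    """Numpy unfold of (B, C, H, W) along one of the four scan paths."""
    if direction >= 2:
        x = x.transpose(0, 1, 3, 2)
    B, C, H, W = x.shape
    seq = x.reshape(B, C, H * W).transpose(0, 2, 1)
    if direction % 2 == 1:
        seq = seq[:, ::-1]
    return seq


def fold_oracle(seq: np.ndarray, direction: int, height: int, width: int) -> np.ndarray:
    if direction % 2 == 1:
        seq = seq[:, ::-1]
    B, L, C = seq.shape
    if direction >= 2:
        return seq.transpose(0, 2, 1).reshape(B, C, width, height).transpose(0, 1, 3, 2)
    return seq.transpose(0, 2, 1).reshape(B, C, height, width)


def ss2d_oracle(x: np.ndarray, ss2d) -> np.ndarray:
    """Four-direction selective scan, recomputed timestep by timestep."""
    B, C, H, W = x.shape
    total = np.zeros_like(x)
    for d in range(4):
        seq = unfold_oracle(x, d)
        y = directional_scan_oracle(seq, getattr(ss2d, f"scan{d}"))
        total += fold_oracle(y, d, H, W)
    return total


def roc_auc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) Mann-Whitney statistic: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def zero_module(module) -> None:
    """Zero every parameter except normalisation scale factors."""
    for name, p in module.named_parameters():
        leaf = name.rsplit(".", 1)[-1]
        if leaf == "weight" and p.data.ndim == 1:
            continue  # norm affine scale stays 1
        p.data[...] = 0.0


def zero_convs(module) -> None:
    """Zero only convolution/linear weights and biases (rank >= 2 weights
    plus their matching biases), leaving norm affines at identity."""
    mods = list(module.modules())
    for m in mods:
        w = getattr(m, "weight", None)
        if w is not None and getattr(w, "data", np.empty(0)).ndim >= 2:
            w.data[...] = 0.0
            b = getattr(m, "bias", None)
            if b is not None:
                b.data[...] = 0.0
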