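"""Differentiable primitives for the autodiff engine.

Each primitive returns a new :class:`Tensor` whose backward closure
accumulates gradients into its parents.  Composite operations (group
norm, softmax, losses, attention blocks) are built from these.
"""

from __future__ import annotations

import builtins

import numpy as np
from scipy import special

from .tensor import Tensor, as_tensor

# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------


def _binary(a, b, fwd, bwd_a, bwd_b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = fwd(a.data, b.data)
    req = a.requires_grad or b.requires_grad
    out = Tensor(out_data, requires_grad=req, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(bwd_a(g, a.data, b.data))
        if b.requires_grad:
            b._accumulate(bwd_b(g, a.data, b.data))

    out._backward = backward
    return out


def add(a, b) -> Tensor:
    return _binary(a, b, lambda x, y: x + y, lambda g, x, y: g, lambda g, x, y: g)


def sub(a, b) -> Tensor:
    return _binary(a, b, lambda x, y: x - y, lambda g, x, y: g, lambda g, x, y: -g)


def mul(a, b) -> Tensor:
    return _binary(a, b, lambda x, y: x * y, lambda g, x, y: g * y, lambda g, x, y: g * x)


def div(a, b) -> Tensor:
    return _binary(
        a,
        b,
        lambda x, y: x / y,
        lambda g, x, y: g / y,
        lambda g, x, y: -g * x / (y * y),
    )


def pow_scalar(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data ** p, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1))

    out._backward = backward
    return out


def _unary(a, fwd, deriv) -> Tensor:
    a = as_tensor(a)
    y = fwd(a.data)
    out = Tensor(y, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * deriv(a.data, y))

    out._backward = backward
    return out


def exp(a) -> Tensor:
    return _unary(a, np.exp, lambda x, y: y)


def log(a) -> Tensor:
    return _unary(a, np.log, lambda x, y: 1.0 / x)


def sqrt(a) -> Tensor:
    return _unary(a, np.sqrt, lambda x, y: 0.5 / y)


def relu(a) -> Tensor:
    return _unary(a, lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(np.float64))


def sigmoid(a) -> Tensor:
    return _unary(a, special.expit, lambda x, y: y * (1.0 - y))


def tanh(a) -> Tensor:
    return _unary(a, np.tanh, lambda x, y: 1.0 - y * y)


def softplus(a) -> Tensor:
    # log(1 + e^x), evaluated stably; derivative is the logistic function
    return _unary(
        a,
        lambda x: np.logaddexp(0.0, x),
        lambda x, y: special.expit(x),
    )


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""

    def fwd(x):
        return 0.5 * x * (1.0 + special.erf(x * _INV_SQRT2))

    def deriv(x, y):
        cdf = 0.5 * (1.0 + special.erf(x * _INV_SQRT2))
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return cdf + x * pdf

    return _unary(a, fwd, deriv)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp with gradient passed through wherever the input is in range."""
    a = as_tensor(a)
    out = Tensor(np.clip(a.data, lo, hi), requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            mask = (a.data >= lo) & (a.data <= hi)
            a._accumulate(g * mask)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------


def _reduced_shape(shape, axis, keepdims):
    if axis is None:
        axes = tuple(range(len(shape)))
    elif isinstance(axis, int):
        axes = (axis % len(shape),)
    else:
        axes = tuple(ax % len(shape) for ax in axis)
    if keepdims:
        return tuple(1 if i in axes else s for i, s in enumerate(shape)), axes
    return tuple(s for i, s in enumerate(shape) if i not in axes), axes


def sum(a, axis=None, keepdims=False) -> Tensor:  # noqa: A001 - mirrors numpy
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    kept_shape, axes = _reduced_shape(a.data.shape, axis, True)
    out = Tensor(out_data, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g.reshape(kept_shape), a.data.shape))

    out._backward = backward
    return out


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    kept_shape, axes = _reduced_shape(a.data.shape, axis, True)
    n = np.prod([a.data.shape[i] for i in axes]) if axes else a.data.size
    out = Tensor(out_data, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g.reshape(kept_shape), a.data.shape) / n)

    out._backward = backward
    return out


def max(a, axis: int, keepdims: bool = False) -> Tensor:  # noqa: A001
    """Max along one axis; the gradient flows to the (first) arg-max entry."""
    a = as_tensor(a)
    axis = axis % a.data.ndim
    idx = np.argmax(a.data, axis=axis)
    out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out_data = np.squeeze(out_data, axis=axis)
    out = Tensor(out_data, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            grad = np.zeros_like(a.data)
            g_k = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(grad, np.expand_dims(idx, axis), g_k, axis=axis)
            a._accumulate(grad)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    out._backward = backward
    return out


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = np.argsort(axes)
    out = Tensor(a.data.transpose(axes), requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    out._backward = backward
    return out


def flip(a, axis: int) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.flip(a.data, axis=axis), requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.flip(g, axis=axis))

    out._backward = backward
    return out


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = builtins.any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# linear layers
# ---------------------------------------------------------------------------


def linear(x, w, b=None) -> Tensor:
    """``y[..., o] = sum_i x[..., i] * w[o, i] (+ b[o])``."""
    x, w = as_tensor(x), as_tensor(w)
    parents = [x, w]
    y = x.data @ w.data.T
    if b is not None:
        b = as_tensor(b)
        parents.append(b)
        y = y + b.data
    req = builtins.any(p.requires_grad for p in parents)
    out = Tensor(y, requires_grad=req, parents=tuple(parents))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data)
        if w.requires_grad:
            gm = g.reshape(-1, g.shape[-1])
            xm = x.data.reshape(-1, x.data.shape[-1])
            w._accumulate(gm.T @ xm)
        if b is not None and b.requires_grad:
            b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# 2D convolution (im2col based, with grouping for depthwise variants)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """View (B, C, Hp, Wp) as (B, C, Ho, Wo, kh, kw) windows."""
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return windows[:, :, ::stride, ::stride]


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2D cross-correlation.

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin // groups, kh, kw); ``b``: (Cout,).
    """
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, H, W = x.data.shape
    Cout, Cin_g, kh, kw = w.data.shape
    if Cin != Cin_g * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {Cin} channels, "
            f"weight expects {Cin_g * groups}"
        )
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, stride)  # (B, Cin, Ho, Wo, kh, kw)
    Ho, Wo = cols.shape[2], cols.shape[3]
    cols_g = cols.reshape(B, groups, Cin_g, Ho, Wo, kh, kw)
    w_g = w.data.reshape(groups, Cout // groups, Cin_g, kh, kw)
    y = np.einsum("bgcijuv,gocuv->bgoij", cols_g, w_g, optimize=True)
    y = y.reshape(B, Cout, Ho, Wo)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        parents.append(b)
        y = y + b.data.reshape(1, Cout, 1, 1)
    req = builtins.any(p.requires_grad for p in parents)
    out = Tensor(y, requires_grad=req, parents=tuple(parents))

    def backward(g):
        g4 = g.reshape(B, groups, Cout // groups, Ho, Wo)
        if w.requires_grad:
            gw = np.einsum("bgcijuv,bgoij->gocuv", cols_g, g4, optimize=True)
            w._accumulate(gw.reshape(Cout, Cin_g, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # scatter window gradients back (col2im)
            t = np.einsum("bgoij,gocuv->bgcijuv", g4, w_g, optimize=True)
            t = t.reshape(B, Cin, Ho, Wo, kh, kw)
            gx = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    gx[:, :, u : u + stride * Ho : stride, v : v + stride * Wo : stride] += t[
                        :, :, :, :, u, v
                    ]
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accumulate(gx)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# bilinear 2x upsampling (align_corners=False convention)
# ---------------------------------------------------------------------------


def _up2_indices(n: int):
    src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    src = np.clip(src, 0.0, n - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n - 1)
    frac = src - i0
    return i0, i1, frac


def upsample2x_bilinear(x) -> Tensor:
    """Double both spatial extents of a (B, C, H, W) tensor bilinearly."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    r0, r1, rf = _up2_indices(H)
    c0, c1, cf = _up2_indices(W)
    rf = rf.reshape(-1, 1)
    xr = (1.0 - rf) * x.data[:, :, r0, :] + rf * x.data[:, :, r1, :]
    y = (1.0 - cf) * xr[:, :, :, c0] + cf * xr[:, :, :, c1]
    out = Tensor(y, requires_grad=x.requires_grad, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gr = np.zeros((B, C, 2 * H, W))
        np.add.at(gr.transpose(3, 0, 1, 2), c0, ((1.0 - cf) * g).transpose(3, 0, 1, 2))
        np.add.at(gr.transpose(3, 0, 1, 2), c1, (cf * g).transpose(3, 0, 1, 2))
        gx = np.zeros_like(x.data)
        np.add.at(gx.transpose(2, 0, 1, 3), r0, ((1.0 - rf) * gr).transpose(2, 0, 1, 3))
        np.add.at(gx.transpose(2, 0, 1, 3), r1, (rf * gr).transpose(2, 0, 1, 3))
        x._accumulate(gx)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# first-order linear recurrence (the selective-scan core)
# ---------------------------------------------------------------------------


def linear_scan(a, u) -> Tensor:
    """Run ``h_t = a_t * h_{t-1} + u_t`` along axis 1, with ``h_0`` prior 0.

    ``a`` and ``u`` have shape (B, L, ...); the recurrence is elementwise in
    the trailing axes.  Backward is the reverse-time adjoint recurrence.
    """
    a, u = as_tensor(a), as_tensor(u)
    if a.data.shape != u.data.shape:
        raise ValueError("linear_scan requires matching shapes")
    L = a.data.shape[1]
    h = np.empty_like(u.data)
    prev = np.zeros_like(u.data[:, 0])
    for t in range(L):
        prev = a.data[:, t] * prev + u.data[:, t]
        h[:, t] = prev
    req = a.requires_grad or u.requires_grad
    out = Tensor(h, requires_grad=req, parents=(a, u))

    def backward(g):
        # dh_t^eff = g_t + a_{t+1} * dh_{t+1}^eff ; da_t = dh_t^eff * h_{t-1}
        gu = np.empty_like(g)
        carry = np.zeros_like(g[:, 0])
        for t in range(L - 1, -1, -1):
            carry = g[:, t] + carry
            gu[:, t] = carry
            carry = carry * a.data[:, t]
        if u.requires_grad:
            u._accumulate(gu)
        if a.requires_grad:
            h_prev = np.concatenate([np.zeros_like(h[:, :1]), h[:, :-1]], axis=1)
            a._accumulate(gu * h_prev)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------


def softmax(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = sub(x, Tensor(x.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return div(e, sum(e, axis=axis, keepdims=True))


def group_norm(x, num_groups: int, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Group normalisation over (B, C, H, W) with per-channel affine."""
    B, C, H, W = x.shape
    if C % num_groups != 0:
        raise ValueError(f"{num_groups} groups do not divide {C} channels")
    xg = reshape(x, (B, num_groups, C // num_groups * H * W))
    mu = mean(xg, axis=2, keepdims=True)
    centred = sub(xg, mu)
    var = mean(mul(centred, centred), axis=2, keepdims=True)
    norm = div(centred, sqrt(add(var, eps)))
    norm = reshape(norm, (B, C, H, W))
    return add(mul(norm, reshape(gamma, (1, C, 1, 1))), reshape(beta, (1, C, 1, 1)))
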