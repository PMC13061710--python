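"""Structured autograd operations: depthwise convolution and SSM scan."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor
from . import scan as _scan

__all__ = ["depthwise_conv2d", "ssm_scan"]


def _dw_patches(x: np.ndarray, k: int) -> np.ndarray:
    """Zero-padded sliding k x k windows of x (B, H, W, C) -> (B, H, W, C, k, k)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    return sliding_window_view(xp, (k, k), axis=(1, 2))


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Per-channel 'same' convolution.

    x: (B, H, W, C); w: (k, k, C); b: (C,) or None.
    Cross-correlation convention (as in deep-learning frameworks).
    """
    x = Tensor._coerce(x)
    w = Tensor._coerce(w)
    k = w.data.shape[0]
    if k % 2 != 1 or w.data.shape[1] != k:
        raise ValueError("depthwise kernel must be square with odd size")
    if w.data.shape[2] != x.data.shape[3]:
        raise ValueError(
            f"kernel channels {w.data.shape[2]} != input channels {x.data.shape[3]}"
        )
    patches = _dw_patches(x.data, k)
    out_data = np.einsum("bhwckl,klc->bhwc", patches, w.data, optimize=True)
    if b is not None:
        b = Tensor._coerce(b)
        out_data = out_data + b.data
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if w.requires_grad:
            w._accum(np.einsum("bhwckl,bhwc->klc", patches, g, optimize=True))
        if x.requires_grad:
            gpatches = _dw_patches(g, k)
            wf = w.data[::-1, ::-1, :]
            x._accum(np.einsum("bhwckl,klc->bhwc", gpatches, wf, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))

    return Tensor._make(out_data, parents, bwd)


def ssm_scan(x: Tensor, a: Tensor, b: Tensor, c: Tensor, d: Tensor) -> Tensor:
    """Linear state-space recurrence along axis 1.

    x: (B, L, C); a, b, c: (C, N) with a in (0, 1); d: (C,).
    Exactly L recurrence steps per (batch, channel) pair.
    """
    x, a, b, c, d = map(Tensor._coerce, (x, a, b, c, d))
    for t in (x, a, b, c, d):
        if not np.all(np.isfinite(t.data)):
            raise ValueError("non-finite SSM scan inputs")
    dt = x.data.dtype
    xd = np.ascontiguousarray(x.data, dtype=dt)
    ad = np.ascontiguousarray(a.data, dtype=dt)
    bd = np.ascontiguousarray(b.data, dtype=dt)
    cd = np.ascontiguousarray(c.data, dtype=dt)
    dd = np.ascontiguousarray(d.data, dtype=dt)

    needs_grad = any(t.requires_grad for t in (x, a, b, c, d))
    from .tensor import is_grad_enabled

    if needs_grad and is_grad_enabled():
        y, s = _scan.scan_forward_with_state(xd, ad, bd, cd, dd)

        def bwd(g):
            gx, ga, gb, gc, gd = _scan.scan_backward(
                np.ascontiguousarray(g, dtype=dt), xd, s, ad, bd, cd, dd
            )
            if x.requires_grad:
                x._accum(gx)
            if a.requires_grad:
                a._accum(ga)
            if b.requires_grad:
                b._accum(gb)
            if c.requires_grad:
                c._accum(gc)
            if d.requires_grad:
                d._accum(gd)

        return Tensor._make(y, (x, a, b, c, d), bwd)
    return Tensor(_scan.scan_forward(xd, ad, bd, cd, dd))
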