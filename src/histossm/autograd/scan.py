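"""Numba kernels for the diagonal linear state-space recurrence.

The recurrence, per batch element and channel, with state dimension N:

    s_t = a * s_{t-1} + b * x_t        (elementwise over the N states)
    y_t = sum_n c_n s_{t,n} + d * x_t

Exactly L update steps are performed per channel, so the cost is linear
in the sequence length.  The backward pass is the adjoint recurrence run
in reverse.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["scan_forward", "scan_forward_with_state", "scan_backward"]


@njit(cache=True)
def scan_forward(x, a, b, c, d):  # pragma: no cover - numba
    """x: (B, L, C); a, b, c: (C, N); d: (C,).  Returns y: (B, L, C)."""
    B, L, C = x.shape
    N = a.shape[1]
    y = np.empty_like(x)
    for bi in range(B):
        for ci in range(C):
            st = np.zeros(N, dtype=x.dtype)
            for t in range(L):
                xt = x[bi, t, ci]
                acc = d[ci] * xt
                for n in range(N):
                    st[n] = a[ci, n] * st[n] + b[ci, n] * xt
                    acc += c[ci, n] * st[n]
                y[bi, t, ci] = acc
    return y


@njit(cache=True)
def scan_forward_with_state(x, a, b, c, d):  # pragma: no cover - numba
    """Like scan_forward but also returns all states s: (B, L, C, N)."""
    B, L, C = x.shape
    N = a.shape[1]
    y = np.empty_like(x)
    s = np.empty((B, L, C, N), dtype=x.dtype)
    for bi in range(B):
        for ci in range(C):
            st = np.zeros(N, dtype=x.dtype)
            for t in range(L):
                xt = x[bi, t, ci]
                acc = d[ci] * xt
                for n in range(N):
                    st[n] = a[ci, n] * st[n] + b[ci, n] * xt
                    s[bi, t, ci, n] = st[n]
                    acc += c[ci, n] * st[n]
                y[bi, t, ci] = acc
    return y, s


@njit(cache=True)
def scan_backward(g, x, s, a, b, c, d):  # pragma: no cover - numba
    """Adjoint of scan_forward.  g: (B, L, C) gradient w.r.t. y.

    Returns (gx, ga, gb, gc, gd).  Uses h_t = dL/ds_t which obeys the
    reverse recurrence h_t = c * g_t + a * h_{t+1}.
    """
    B, L, C = x.shape
    N = a.shape[1]
    gx = np.zeros_like(x)
    ga = np.zeros_like(a)
    gb = np.zeros_like(b)
    gc = np.zeros_like(c)
    gd = np.zeros_like(d)
    for bi in range(B):
        for ci in range(C):
            h = np.zeros(N, dtype=x.dtype)
            for t in range(L - 1, -1, -1):
                gt = g[bi, t, ci]
                xt = x[bi, t, ci]
                gd[ci] += gt * xt
                gxi = d[ci] * gt
                for n in range(N):
                    gc[ci, n] += gt * s[bi, t, ci, n]
                    h[n] = c[ci, n] * gt + a[ci, n] * h[n]
                    sprev = s[bi, t - 1, ci, n] if t > 0 else 0.0
                    ga[ci, n] += h[n] * sprev
                    gb[ci, n] += h[n] * xt
                    gxi += b[ci, n] * h[n]
                gx[bi, t, ci] = gxi
    return gx, ga, gb, gc, gd
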