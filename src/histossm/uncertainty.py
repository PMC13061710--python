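"""Entropy-based per-position uncertainty and dynamic fusion weights.

For a feature map F (H, W, C) the channel distribution at each position
is p_c = (F_c^2 + eps) / (sum_c' F_c'^2 + C*eps) and the uncertainty is
the Shannon entropy U = -sum_c p_c ln p_c, bounded by ln C.  The map is
resized (bilinear) to each decoder resolution and converted to a
per-position local-branch weight alpha' = alpha0 * exp(-lambda * U).

All functions accept either autograd tensors (differentiable path used
inside the network) or plain NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = ["UdParams", "feature_entropy", "resize_uncertainty",
           "adjust_weight", "bilinear_matrix"]

DEFAULT_EPS = 1e-8


@dataclass
class UdParams:
    """alpha0: base local-branch weight in (0, 1); lam: sensitivity > 0."""

    alpha0: float = 0.5
    lam: float = 1.0
    eps: float = DEFAULT_EPS

    def __post_init__(self):
        if not 0.0 < self.alpha0 < 1.0:
            raise ValueError("alpha0 must lie strictly in (0, 1)")
        if self.lam <= 0.0:
            raise ValueError("lambda must be positive")


def _wrap(x):
    return (x, True) if isinstance(x, Tensor) else (Tensor(np.asarray(x, dtype=float)), False)


def feature_entropy(f_enc, eps: float = DEFAULT_EPS):
    """Per-position entropy of the squared-intensity channel distribution.

    f_enc: (..., H, W, C) tensor/array; returns (..., H, W) with values
    in [0, ln C].  eps guards the all-zero vector (which then yields the
    uniform distribution, i.e. maximal uncertainty).
    """
    x, was_tensor = _wrap(f_enc)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("feature map must be finite")
    c = x.shape[-1]
    sq = x * x
    denom = sq.sum(axis=-1, keepdims=True) + (c * eps)
    p = (sq + eps) / denom
    u = -(p * p.log()).sum(axis=-1)
    return u if was_tensor else u.data


def bilinear_matrix(src: int, dst: int, dtype=float) -> np.ndarray:
    """(dst, src) interpolation matrix; endpoints map to endpoints."""
    m = np.zeros((dst, src), dtype=dtype)
    if src == 1:
        m[:, 0] = 1.0
        return m
    pos = np.linspace(0.0, src - 1.0, dst)
    lo = np.clip(np.floor(pos).astype(int), 0, src - 2)
    frac = pos - lo
    m[np.arange(dst), lo] = 1.0 - frac
    m[np.arange(dst), lo + 1] = frac
    return m


def resize_uncertainty(u, target: tuple[int, int]):
    """Bilinear resize of a (..., H, W) map to target (H', W')."""
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError("target size must be at least 1x1")
    x, was_tensor = _wrap(u)
    h, w = x.shape[-2], x.shape[-1]
    rh = Tensor(bilinear_matrix(h, th, dtype=x.dtype))
    rw = Tensor(bilinear_matrix(w, tw, dtype=x.dtype).T)
    out = rh @ x @ rw  # broadcasting handles an optional leading batch axis
    return out if was_tensor else out.data


def adjust_weight(u, params: UdParams, alpha0=None):
    """Per-position local-branch weight alpha' = alpha0 * exp(-lambda*U).

    Strictly decreasing in U; equals alpha0 where U = 0; always in
    (0, alpha0].  A learnable scalar Tensor may be supplied via `alpha0`
    to override the constant in `params`.
    """
    if params.lam <= 0.0:
        raise ValueError("lambda must be positive")
    x, was_tensor = _wrap(u)
    if np.any(x.data < 0):
        raise ValueError("uncertainty must be nonnegative")
    a0 = params.alpha0 if alpha0 is None else alpha0
    out = a0 * (x * (-params.lam)).exp()
    return out if was_tensor else out.data
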