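"""Global-local fusion block.

Each block combines
  * a local branch: depthwise separable convolution (per-channel k x k
    spatial filter followed by a 1 x 1 channel-mixing convolution),
  * a global branch: a bidirectional diagonal linear state-space scan
    over the row-major token sequence of the local feature map, and
  * a fusion stage: a convex combination ``alpha * local +
    (1 - alpha) * global`` where ``alpha`` comes from channel attention
    (encoder mode), from an externally supplied spatial weight map
    (decoder mode), or is a fixed constant (ablation mode).

Functional single-image operations (NumPy in / NumPy out) are exposed
alongside the trainable :class:`GMambaBlock`; both run the same kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, depthwise_conv2d, ssm_scan as _ssm_scan_op
from .autograd.nn import DepthwiseConv2d, Dropout, LayerNorm, Linear, Module

__all__ = [
    "SsmParams",
    "GMambaConfig",
    "depthwise_separable_conv",
    "flatten_rows",
    "unflatten",
    "ssm_scan",
    "bidirectional_global_extract",
    "channel_attention",
    "fuse",
    "gmamba_block",
    "dsc_mac_count",
    "dense_conv_mac_count",
    "GMambaBlock",
    "SsmOnlyBlock",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SsmParams:
    """Per-channel diagonal state-space parameters.

    a: (C, N) transition, each entry in [0, 1) for stability (0 is the
    memoryless limit); b: (C, N) input weights; c: (C, N) output
    weights; d: (C,) passthrough.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.a.ndim != 2 or self.a.shape != self.b.shape or self.a.shape != self.c.shape:
            raise ValueError("a, b, c must share shape (C, N)")
        if self.d.shape != (self.a.shape[0],):
            raise ValueError("d must have shape (C,)")
        for arr in (self.a, self.b, self.c, self.d):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite SSM parameters")
        if np.any(self.a < 0.0) or np.any(self.a >= 1.0):
            raise ValueError("transition entries must lie in [0, 1)")

    @property
    def state_dim(self) -> int:
        return self.a.shape[1]


@dataclass
class GMambaConfig:
    channels: int
    out_channels: int | None = None
    kernel: int = 3
    state_dim: int = 16
    mode: str = "channel"          # channel | spatial | fixed
    fixed_alpha: float = 0.5
    selective: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.out_channels is None:
            self.out_channels = self.channels
        if self.mode not in ("channel", "spatial", "fixed"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")


# ---------------------------------------------------------------------------
# functional operations (single image, NumPy in / out)
# ---------------------------------------------------------------------------

def depthwise_separable_conv(f_in: np.ndarray, dw_kernels: np.ndarray,
                             pw_weights: np.ndarray,
                             b_dw: np.ndarray | None = None,
                             b_pw: np.ndarray | None = None) -> np.ndarray:
    """Depthwise (k x k per-channel, 'same') then pointwise (1 x 1) convolution.

    f_in: (H, W, C_in); dw_kernels: (k, k, C_in); pw_weights: (C_in, C_out).
    """
    f_in = np.asarray(f_in, dtype=float)
    dw_kernels = np.asarray(dw_kernels, dtype=float)
    pw_weights = np.asarray(pw_weights, dtype=float)
    c_in = f_in.shape[2]
    if pw_weights.shape[0] != c_in:
        raise ValueError("pointwise weight rows must equal input channels")
    b_dw = np.zeros(c_in) if b_dw is None else np.asarray(b_dw, dtype=float)
    b_pw = (np.zeros(pw_weights.shape[1]) if b_pw is None
            else np.asarray(b_pw, dtype=float))
    x = Tensor(f_in[None])
    dw = depthwise_conv2d(x, Tensor(dw_kernels), Tensor(b_dw))
    out = dw @ Tensor(pw_weights) + Tensor(b_pw)
    return out.data[0]


def flatten_rows(f: np.ndarray) -> np.ndarray:
    """(H, W, C) -> (H*W, C) in row-major token order."""
    f = np.asarray(f)
    h, w, c = f.shape
    return f.reshape(h * w, c)


def unflatten(seq: np.ndarray, origin_shape: tuple[int, int]) -> np.ndarray:
    """(L, C) -> (H, W, C); requires L == H*W."""
    seq = np.asarray(seq)
    h, w = origin_shape
    if seq.shape[0] != h * w:
        raise ValueError(f"sequence length {seq.shape[0]} != H*W = {h * w}")
    return seq.reshape(h, w, seq.shape[1])


def ssm_scan(x: np.ndarray, params: SsmParams, direction: str = "forward") -> np.ndarray:
    """Run the recurrence over x: (L, C).  Backward direction reverses the
    input, scans, and reverses the output."""
    x = np.asarray(x, dtype=float)
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    xs = x[::-1] if direction == "backward" else x
    y = _ssm_scan_op(Tensor(np.ascontiguousarray(xs)[None]),
                     params.a, params.b, params.c, params.d).data[0]
    return y[::-1] if direction == "backward" else y


def bidirectional_global_extract(f: np.ndarray, params_fwd: SsmParams,
                                 params_bwd: SsmParams,
                                 projection: np.ndarray,
                                 bias: np.ndarray | None = None) -> np.ndarray:
    """Bidirectional scan over the row-major sequence of f (H, W, C),
    concatenated along channels and linearly projected 2C -> C."""
    f = np.asarray(f, dtype=float)
    h, w, c = f.shape
    projection = np.asarray(projection, dtype=float)
    if projection.shape != (2 * c, c):
        raise ValueError(f"projection must be (2C, C) = {(2 * c, c)}")
    seq = flatten_rows(f)
    yf = ssm_scan(seq, params_fwd, "forward")
    yb = ssm_scan(seq, params_bwd, "backward")
    y = np.concatenate([yf, yb], axis=1) @ projection
    if bias is not None:
        y = y + np.asarray(bias, dtype=float)
    return unflatten(y, (h, w))


def channel_attention(f_local: np.ndarray, f_global: np.ndarray,
                      w_att: np.ndarray, b_att: np.ndarray) -> np.ndarray:
    """Per-channel fusion weights: sigmoid(GAP(local ++ global) @ W + b)."""
    f_local = np.asarray(f_local, dtype=float)
    f_global = np.asarray(f_global, dtype=float)
    if f_local.shape != f_global.shape:
        raise ValueError("local/global shape mismatch")
    pooled = np.concatenate([f_local, f_global], axis=-1).mean(axis=(0, 1))
    z = pooled @ np.asarray(w_att, dtype=float) + np.asarray(b_att, dtype=float)
    from scipy.special import expit

    return expit(z)


def fuse(f_local: np.ndarray, f_global: np.ndarray, alpha) -> np.ndarray:
    """Convex combination alpha*local + (1-alpha)*global.

    alpha may be a scalar, a per-channel vector (C,), or a per-position
    map (H, W); it is broadcast over the missing axes.
    """
    f_local = np.asarray(f_local, dtype=float)
    f_global = np.asarray(f_global, dtype=float)
    if f_local.shape != f_global.shape:
        raise ValueError("local/global shape mismatch")
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0.0) or np.any(alpha > 1.0):
        raise ValueError("fusion weights must lie in [0, 1]")
    if alpha.ndim == 2:  # spatial map -> broadcast over channels
        alpha = alpha[:, :, None]
    return alpha * f_local + (1.0 - alpha) * f_global


def gmamba_block(f_in: np.ndarray, config: GMambaConfig,
                 alpha_map: np.ndarray | None = None) -> np.ndarray:
    """Apply a freshly initialized block (seeded from config) to one image."""
    block = GMambaBlock(config.channels, config.out_channels, config.kernel,
                        config.state_dim, np.random.default_rng(config.seed),
                        mode=config.mode, fixed_alpha=config.fixed_alpha,
                        selective=config.selective, dtype=np.float64)
    block.eval()
    x = Tensor(np.asarray(f_in, dtype=float)[None])
    am = None if alpha_map is None else Tensor(np.asarray(alpha_map, dtype=float)[None])
    return block(x, alpha_map=am).data[0]


def dsc_mac_count(h: int, w: int, c_in: int, c_out: int, k: int) -> int:
    """Multiply-accumulate count of the separable factorization."""
    return (k * k * c_in + c_in * c_out) * h * w


def dense_conv_mac_count(h: int, w: int, c_in: int, c_out: int, k: int) -> int:
    """Multiply-accumulate count of the equivalent dense convolution."""
    return k * k * c_in * c_out * h * w


# ---------------------------------------------------------------------------
# trainable blocks
# ---------------------------------------------------------------------------

class _SsmBank(Module):
    """Learnable per-channel diagonal SSM; transition kept in (0, 1) via
    a = exp(-softplus(a_raw))."""

    def __init__(self, channels: int, state_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.a_raw = Tensor(
            rng.uniform(-0.5, 1.5, size=(channels, state_dim)).astype(dtype),
            requires_grad=True,
        )
        scale = 1.0 / np.sqrt(state_dim)
        self.b = Tensor(rng.normal(0, scale, (channels, state_dim)).astype(dtype),
                        requires_grad=True)
        self.c = Tensor(rng.normal(0, scale, (channels, state_dim)).astype(dtype),
                        requires_grad=True)
        self.d = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)

    def transition(self) -> Tensor:
        return (-(self.a_raw.softplus())).exp()

    def forward(self, x: Tensor) -> Tensor:  # x: (B, L, C)
        return _ssm_scan_op(x, self.transition(), self.b, self.c, self.d)


class _BidirectionalGlobal(Module):
    """Forward + backward scans over row-major tokens, concat, project 2C->C."""

    def __init__(self, channels: int, state_dim: int, rng: np.random.Generator,
                 selective: bool = False, dtype=np.float32):
        super().__init__()
        self.fwd = _SsmBank(channels, state_dim, rng, dtype)
        self.bwd = _SsmBank(channels, state_dim, rng, dtype)
        self.proj = Linear(2 * channels, channels, rng, dtype=dtype)
        self.gate = Linear(channels, channels, rng, dtype=dtype) if selective else None

    def forward(self, x: Tensor) -> Tensor:  # x: (B, H, W, C)
        bsz, h, w, c = x.shape
        seq = x.reshape(bsz, h * w, c)
        if self.gate is not None:
            seq = seq * self.gate(seq).sigmoid()
        yf = self.fwd(seq)
        yb = self.bwd(seq[:, ::-1, :])[:, ::-1, :]
        y = self.proj(concat([yf, yb], axis=-1))
        return y.reshape(bsz, h, w, c)


class GMambaBlock(Module):
    """Pre-norm residual block fusing the local (separable-convolution)
    and global (bidirectional scan) branches.

    mode='channel': fusion weights from channel attention (encoder).
    mode='spatial': fusion weights supplied per position via `alpha_map`
                    (decoder, driven by the uncertainty module).
    mode='fixed':   constant fusion weight `fixed_alpha` (ablation).
    """

    def __init__(self, in_channels: int, out_channels: int | None,
                 kernel: int, state_dim: int, rng: np.random.Generator,
                 mode: str = "channel", fixed_alpha: float = 0.5,
                 selective: bool = False, dtype=np.float32):
        super().__init__()
        out_channels = in_channels if out_channels is None else out_channels
        if mode not in ("channel", "spatial", "fixed"):
            raise ValueError(f"unknown fusion mode {mode!r}")
        if not 0.0 <= fixed_alpha <= 1.0:
            raise ValueError("fixed_alpha must lie in [0, 1]")
        self.mode = mode
        self.fixed_alpha = fixed_alpha
        self.norm = LayerNorm(in_channels, dtype=dtype)
        self.dw = DepthwiseConv2d(in_channels, kernel, rng, dtype=dtype)
        self.pw = Linear(in_channels, out_channels, rng, dtype=dtype)
        self.glob = _BidirectionalGlobal(out_channels, state_dim, rng,
                                         selective=selective, dtype=dtype)
        self.att = (Linear(2 * out_channels, out_channels, rng, dtype=dtype)
                    if mode == "channel" else None)
        self.res_proj = (Linear(in_channels, out_channels, rng, bias=False,
                                dtype=dtype)
                         if in_channels != out_channels else None)

    def forward(self, x: Tensor, alpha_map: Tensor | None = None) -> Tensor:
        h = self.norm(x)
        local = self.pw(self.dw(h)).gelu()
        glob = self.glob(local)
        if self.mode == "channel":
            pooled = concat([local, glob], axis=-1).mean(axis=(1, 2))
            alpha = self.att(pooled).sigmoid()
            alpha = alpha.reshape(alpha.shape[0], 1, 1, alpha.shape[1])
        elif self.mode == "spatial":
            if alpha_map is None:
                raise ValueError("spatial mode requires an alpha_map")
            if np.any(alpha_map.data < 0) or np.any(alpha_map.data > 1):
                raise ValueError("alpha_map entries must lie in [0, 1]")
            alpha = alpha_map.reshape(*alpha_map.shape, 1)
        else:
            alpha = Tensor(np.asarray(self.fixed_alpha, dtype=x.dtype))
        fused = alpha * local + (1.0 - alpha) * glob
        res = x if self.res_proj is None else self.res_proj(x)
        return res + fused


class SsmOnlyBlock(Module):
    """Ablation block: global scan branch only, no local convolution and
    no fusion (plain vision-SSM token mixer with residual)."""

    def __init__(self, in_channels: int, out_channels: int | None,
                 state_dim: int, rng: np.random.Generator,
                 selective: bool = False, dtype=np.float32):
        super().__init__()
        out_channels = in_channels if out_channels is None else out_channels
        self.norm = LayerNorm(in_channels, dtype=dtype)
        self.inp = (Linear(in_channels, out_channels, rng, dtype=dtype)
                    if in_channels != out_channels else None)
        self.glob = _BidirectionalGlobal(out_channels, state_dim, rng,
                                         selective=selective, dtype=dtype)
        self.res_proj = (Linear(in_channels, out_channels, rng, bias=False,
                                dtype=dtype)
                         if in_channels != out_channels else None)

    def forward(self, x: Tensor, alpha_map: Tensor | None = None) -> Tensor:
        h = self.norm(x)
        if self.inp is not None:
            h = self.inp(h)
        glob = self.glob(h)
        res = x if self.res_proj is None else self.res_proj(x)
        return res + glob
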