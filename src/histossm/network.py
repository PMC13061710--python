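"""Encoder-decoder assembly with uncertainty-modulated decoder fusion.

Layout for the default configuration (224 x 224 x 3 input, base 64):

  stem (stride-2 conv)        -> 112 x 112 x 64
  4 encoder blocks, 3 stride-2 downsamplings doubling channels
                              -> bottleneck 14 x 14 x 512
  entropy uncertainty map from the bottleneck
  decoder mirrors the encoder (transposed-conv upsamplings, skip
  concatenation + pointwise reduction, uncertainty-weighted blocks)
  final stem-mirror upsampling -> 224 x 224 x 64
  head: GAP -> dropout -> affine -> softmax (64-d pooled vector)
  auxiliary head: pointwise conv + sigmoid -> local probability map

The downsampling layers are 2x2 stride-2 convolutions expressed as
space-to-depth + channel mixing; upsamplings are the exact transpose
(channel mixing + depth-to-space), i.e. 2x2 stride-2 transposed
convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor, concat, no_grad
from .autograd.nn import Dropout, Linear, Module
from .gmamba import GMambaBlock, SsmOnlyBlock
from .uncertainty import UdParams, adjust_weight, feature_entropy, resize_uncertainty

__all__ = ["ModelConfig", "ForwardOutput", "Model", "build_model",
           "make_variant", "VARIANTS"]

VARIANTS = {
    1: "full model",
    2: "no uncertainty modulation (fixed alpha = 0.5 in decoder fusion)",
    3: "scan-only blocks (no local convolution branch)",
    4: "no skip connections",
    5: "scan-only blocks and no uncertainty modulation",
}


@dataclass
class ModelConfig:
    base_channels: int = 64
    n_levels: int = 4
    tile_size: int = 224
    state_dim: int = 16
    num_classes: int = 2
    dropout: float = 0.1
    kernel: int = 3
    selective: bool = False
    # uncertainty-driven decoder fusion
    ud: bool = True
    # fusion rule for decoder blocks when ud is off: 'fixed' (constant
    # fixed_alpha, the ablation-variant definition) or 'channel'
    # (channel attention, as in the encoder)
    no_ud_mode: str = "fixed"
    fixed_alpha: float = 0.5
    ud_lambda: float = 1.0
    alpha0_init: float = 0.5
    ud_eps: float = 1e-8
    # ablation switches
    use_skips: bool = True
    ssm_only: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.tile_size % (2 ** self.n_levels) != 0:
            raise ValueError(
                f"tile_size {self.tile_size} must be divisible by "
                f"2^{self.n_levels} (stem + {self.n_levels - 1} downsamplings)"
            )
        if self.n_levels < 1:
            raise ValueError("need at least one level")
        if self.no_ud_mode not in ("fixed", "channel"):
            raise ValueError("no_ud_mode must be 'fixed' or 'channel'")

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** (self.n_levels - 1)


@dataclass
class ForwardOutput:
    """class_probabilities: (num_classes,) summing to 1;
    uncertainty_map: bottleneck-resolution entropy map;
    local_prob_map: per-position abnormal probability at output
    resolution (drives the error map of the calibration loss)."""

    class_probabilities: np.ndarray
    uncertainty_map: np.ndarray
    local_prob_map: np.ndarray


class _SpaceToDepth(Module):
    """2x2 space-to-depth + channel mixing == 2x2 stride-2 convolution."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        super().__init__()
        self.proj = Linear(4 * in_ch, out_ch, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        x = x.reshape(b, h // 2, 2, w // 2, 2, c)
        x = x.transpose((0, 1, 3, 2, 4, 5)).reshape(b, h // 2, w // 2, 4 * c)
        return self.proj(x)


class _DepthToSpace(Module):
    """Channel mixing + 2x2 depth-to-space == 2x2 stride-2 transposed conv."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        super().__init__()
        self.out_ch = out_ch
        self.proj = Linear(in_ch, 4 * out_ch, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, _ = x.shape
        x = self.proj(x).reshape(b, h, w, 2, 2, self.out_ch)
        return x.transpose((0, 1, 3, 2, 4, 5)).reshape(b, 2 * h, 2 * w, self.out_ch)


class Model(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        cfg = config
        rng = np.random.default_rng(cfg.seed)
        ch = [cfg.base_channels * 2**i for i in range(cfg.n_levels)]
        self._channels = ch

        def make_block(c: int, mode: str):
            if cfg.ssm_only:
                return SsmOnlyBlock(c, c, cfg.state_dim, rng,
                                    selective=cfg.selective)
            return GMambaBlock(c, c, cfg.kernel, cfg.state_dim, rng, mode=mode,
                               fixed_alpha=cfg.fixed_alpha,
                               selective=cfg.selective)

        self.stem = _SpaceToDepth(3, ch[0], rng)
        self.enc_blocks = [make_block(c, "channel") for c in ch]
        self.downs = [_SpaceToDepth(ch[i], ch[i + 1], rng)
                      for i in range(cfg.n_levels - 1)]

        dec_mode = "spatial" if cfg.ud else cfg.no_ud_mode
        self.dec_blocks = [make_block(c, dec_mode) for c in ch]
        self.ups = [_DepthToSpace(ch[i + 1], ch[i], rng)
                    for i in range(cfg.n_levels - 1)]
        self.skip_reduce = ([Linear(2 * c, c, rng) for c in ch[:-1]]
                            if cfg.use_skips else None)
        self.final_up = _DepthToSpace(ch[0], ch[0], rng)
        # per-decoder-level learnable base weight, alpha0 = sigmoid(raw)
        a0 = float(cfg.alpha0_init)
        if not 0.0 < a0 < 1.0:
            raise ValueError("alpha0_init must lie in (0, 1)")
        raw0 = np.log(a0 / (1.0 - a0))
        self.alpha0_raw = [Tensor(np.asarray(raw0, dtype=np.float32),
                                  requires_grad=True)
                           for _ in ch]
        self.dropout = Dropout(cfg.dropout, rng)
        self.head = Linear(ch[0], cfg.num_classes, rng)
        self.aux_head = Linear(ch[0], 1, rng)
        # populated on every forward pass (shape bookkeeping)
        self.bottleneck_shape: tuple[int, int, int] | None = None
        self.pooled_dim: int | None = None

    # -- forward -------------------------------------------------------
    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """x: (B, H, W, 3) -> (probs (B, K), uncertainty (B, hb, wb),
        local probability map (B, H, W))."""
        cfg = self.config
        if x.shape[1] != cfg.tile_size or x.shape[2] != cfg.tile_size:
            raise ValueError(
                f"expected {cfg.tile_size}x{cfg.tile_size} input, "
                f"got {x.shape[1]}x{x.shape[2]}"
            )
        h = self.stem(x)
        skips = []
        for i, block in enumerate(self.enc_blocks):
            h = block(h)
            skips.append(h)
            if i < len(self.downs):
                h = self.downs[i](h)
        f_enc = h  # bottleneck
        self.bottleneck_shape = tuple(f_enc.shape[1:])
        u = feature_entropy(f_enc, eps=cfg.ud_eps)  # (B, hb, wb)

        d = f_enc
        for lvl in range(cfg.n_levels - 1, -1, -1):
            if lvl < cfg.n_levels - 1:
                d = self.ups[lvl](d)
                if self.skip_reduce is not None:
                    d = self.skip_reduce[lvl](concat([d, skips[lvl]], axis=-1))
            alpha_map = None
            if cfg.ud and not cfg.ssm_only:
                u_lvl = resize_uncertainty(u, (d.shape[1], d.shape[2]))
                alpha0 = self.alpha0_raw[lvl].sigmoid()
                alpha_map = adjust_weight(
                    u_lvl, UdParams(0.5, cfg.ud_lambda, cfg.ud_eps), alpha0=alpha0
                )
            d = self.dec_blocks[lvl](d, alpha_map=alpha_map)
        d = self.final_up(d)  # (B, H, W, base)

        pooled = d.mean(axis=(1, 2))
        self.pooled_dim = int(pooled.shape[-1])
        logits = self.head(self.dropout(pooled))
        probs = logits.softmax(axis=-1)
        local = self.aux_head(d).sigmoid()
        local = local.reshape(local.shape[0], local.shape[1], local.shape[2])
        return probs, u, local

    # -- inference convenience -----------------------------------------
    def predict(self, pixels: np.ndarray) -> ForwardOutput:
        """Single-tile eval-mode forward pass on an (H, W, 3) array."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                x = Tensor(np.asarray(pixels, dtype=np.float32)[None])
                probs, u, local = self.forward(x)
        finally:
            if was_training:
                self.train()
        return ForwardOutput(probs.data[0], u.data[0], local.data[0])

    def predict_batch(self, pixels: np.ndarray):
        """Eval-mode forward on (B, H, W, 3); returns NumPy triple."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                probs, u, local = self.forward(
                    Tensor(np.asarray(pixels, dtype=np.float32))
                )
        finally:
            if was_training:
                self.train()
        return probs.data, u.data, local.data

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


def build_model(config: ModelConfig | None = None) -> Model:
    return Model(config or ModelConfig())


def make_variant(config: ModelConfig, variant: int) -> Model:
    """Ablation variants: 1 full; 2 fixed decoder fusion (alpha = 0.5);
    3 scan-only blocks; 4 no skip connections; 5 = 2 + 3."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant}; choose from 1..5")
    if variant == 1:
        cfg = config
    elif variant == 2:
        cfg = replace(config, ud=False, fixed_alpha=0.5)
    elif variant == 3:
        cfg = replace(config, ssm_only=True)
    elif variant == 4:
        cfg = replace(config, use_skips=False)
    else:
        cfg = replace(config, ud=False, ssm_only=True)
    return Model(cfg)
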