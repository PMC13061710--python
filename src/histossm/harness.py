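"""Training, evaluation, and ablation harness.

Defaults follow the reference training configuration (AdamW 1e-4,
cosine annealing with 5 linear warm-up epochs down to 1e-6, batch 32,
100 epochs, early stopping patience 10, combined loss with gamma = 0.1,
label smoothing 0.1).  A `desk_profile` helper shrinks everything to a
single-CPU scale (64-pixel tiles, 8 base channels, few epochs) used by
the test-suite and the synthetic end-to-end runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .autograd import Tensor
from .autograd.optim import AdamW, clip_grad_norm
from .data_pipeline import (AugmentParams, SplitManifest, augment,
                            oversample_minority, patient_independent_split)
from .losses_metrics import (cross_entropy, error_map, evaluate_predictions,
                             ual_loss, ual_loss_batch)
from .network import Model, ModelConfig, make_variant
from .synthetic_data import RgbTile
from .uncertainty import resize_uncertainty

__all__ = ["TrainConfig", "RunRecord", "lr_schedule", "train", "evaluate",
           "run_ablation", "desk_profile", "load_config", "save_checkpoint",
           "load_checkpoint"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr: float = 1e-4
    min_lr: float = 1e-6
    weight_decay: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    warmup_epochs: int = 5
    batch_size: int = 32
    epochs: int = 100
    early_stopping_patience: int = 10
    gamma: float = 0.1
    ual_metric: str = "pearson"
    label_smoothing: float = 0.1
    class_weighting: bool = True
    grad_clip: float = 1.0
    seed: int = 0
    augment: AugmentParams = field(default_factory=AugmentParams)

    def __post_init__(self):
        if not self.lr > self.min_lr > 0:
            raise ValueError("require lr > min_lr > 0")
        if not 0 <= self.warmup_epochs < self.epochs:
            raise ValueError("warm-up must be shorter than training")


@dataclass
class RunRecord:
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = -np.inf
    stopped_early: bool = False

    def append(self, row: dict):
        if self.history and row["epoch"] <= self.history[-1]["epoch"]:
            raise ValueError("epochs must be monotone")
        self.history.append(row)


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Linear ramp 0 -> lr over the warm-up epochs, then cosine decay to
    min_lr at the final epoch."""
    if not 0 <= epoch < config.epochs:
        raise ValueError("epoch out of range")
    if config.warmup_epochs > 0 and epoch < config.warmup_epochs:
        return config.lr * epoch / config.warmup_epochs
    last = config.epochs - 1
    if last == config.warmup_epochs:
        return config.lr
    t = (epoch - config.warmup_epochs) / (last - config.warmup_epochs)
    return config.min_lr + 0.5 * (config.lr - config.min_lr) * (1 + np.cos(np.pi * t))


def desk_profile(tile_size: int = 64, epochs: int = 12,
                 seed: int = 0) -> tuple[ModelConfig, TrainConfig]:
    """Single-CPU profile used for synthetic-cohort experiments."""
    mcfg = ModelConfig(base_channels=8, state_dim=8, tile_size=tile_size,
                       dropout=0.1, seed=seed)
    tcfg = TrainConfig(lr=3e-3, min_lr=1e-4, warmup_epochs=2, epochs=epochs,
                       early_stopping_patience=max(4, epochs), batch_size=32,
                       seed=seed)
    return mcfg, tcfg


def _class_weights(labels: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency weights normalized to mean 1."""
    n = len(labels)
    n1 = int(np.sum(labels))
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        return (1.0, 1.0)
    w0, w1 = n / (2.0 * n0), n / (2.0 * n1)
    return (w0, w1)


def _batch_loss(model: Model, px: np.ndarray, labels: np.ndarray,
                cfg: TrainConfig, weights) -> tuple[Tensor, float, float]:
    probs, u, local = model(Tensor(px))
    p_abn = probs[:, 1]
    cel = cross_entropy(p_abn, labels, class_weights=weights,
                        label_smoothing=cfg.label_smoothing)
    use_ual = cfg.gamma > 0 and model.config.ud
    if use_ual:
        u_full = resize_uncertainty(u, (local.shape[1], local.shape[2]))
        e = _error_maps(local, labels)
        ual = ual_loss_batch(u_full, e, cfg.ual_metric)
        total = cel + cfg.gamma * ual
        return total, float(cel.item()), float(ual.item())
    return cel, float(cel.item()), 0.0


def _error_maps(local: Tensor, labels: np.ndarray) -> Tensor:
    from .autograd import stack

    return stack([error_map(local[i], float(labels[i]))
                  for i in range(local.shape[0])], axis=0)


def train(model: Model, train_tiles: list[RgbTile], val_tiles: list[RgbTile],
          config: TrainConfig | None = None,
          checkpoint_path: str | None = None) -> RunRecord:
    """Fit the model; monitors validation F1 with early stopping and
    restores the best-F1 parameters before returning."""
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    labels_pre = np.array([t.label for t in train_tiles])
    weights = _class_weights(labels_pre) if cfg.class_weighting else None

    tiles = oversample_minority(train_tiles, seed=cfg.seed)
    labels = np.array([t.label for t in tiles])
    n = len(tiles)
    record = RunRecord()
    opt = AdamW(model.parameters(), lr=cfg.lr, betas=(cfg.beta1, cfg.beta2),
                eps=cfg.adam_eps, weight_decay=cfg.weight_decay)
    best_state = None
    bad_epochs = 0
    for epoch in range(cfg.epochs):
        opt.lr = lr_schedule(epoch, cfg)
        model.train()
        order = rng.permutation(n)
        ep_cel = ep_ual = ep_total = 0.0
        nb = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [augment(tiles[i], rng, cfg.augment) for i in idx]
            px = np.stack([t.pixels for t in batch]).astype(np.float32)
            total, cel_v, ual_v = _batch_loss(model, px, labels[idx], cfg, weights)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.zero_grad()
            total.backward()
            if cfg.grad_clip > 0:
                clip_grad_norm(opt.params, cfg.grad_clip)
            opt.step()
            ep_cel += cel_v
            ep_ual += ual_v
            ep_total += float(total.item())
            nb += 1
        val = evaluate(model, val_tiles, gamma=cfg.gamma,
                       ual_metric=cfg.ual_metric)
        row = {"epoch": epoch, "lr": opt.lr, "train_cel": ep_cel / nb,
               "train_ual": ep_ual / nb, "train_total": ep_total / nb,
               "val_f1": val["f1"], "val_accuracy": val["accuracy"]}
        record.append(row)
        log.info("epoch %d lr %.2e loss %.4f val_f1 %.4f", epoch, opt.lr,
                 row["train_total"], row["val_f1"])
        if val["f1"] > record.best_val_f1:
            record.best_val_f1 = val["f1"]
            record.best_epoch = epoch
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.early_stopping_patience:
                record.stopped_early = True
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, train_config=cfg, record=record)
    return record


def evaluate(model: Model, tiles: list[RgbTile], batch_size: int = 32,
             gamma: float = 0.1, ual_metric: str = "pearson") -> dict:
    """Augmentation- and oversampling-free evaluation.  Returns the
    metric bundle plus the mean per-image uncertainty-error Pearson
    correlation."""
    if not tiles:
        raise ValueError("no tiles to evaluate")
    scores, labels, rhos = [], [], []
    for start in range(0, len(tiles), batch_size):
        chunk = tiles[start:start + batch_size]
        px = np.stack([t.pixels for t in chunk]).astype(np.float32)
        probs, u, local = model.predict_batch(px)
        scores.extend(probs[:, 1].tolist())
        labels.extend(t.label for t in chunk)
        u_full = resize_uncertainty(u, local.shape[1:3])
        for i, t in enumerate(chunk):
            e = np.abs(local[i] - t.label)
            rhos.append(1.0 - ual_loss(u_full[i], e, "pearson"))
    out = evaluate_predictions(np.array(scores), np.array(labels))
    out["mean_ue_pearson"] = float(np.mean(rhos))
    out["gamma"] = gamma
    out["ual_metric"] = ual_metric
    return out


def run_ablation(model_cfg: ModelConfig, train_tiles, val_tiles, test_tiles,
                 variants=(1, 2, 3, 4, 5), seeds=(0,),
                 train_cfg: TrainConfig | None = None) -> list[dict]:
    """Train and evaluate each ablation variant over the given seeds;
    one result row per (variant, seed)."""
    base_tcfg = train_cfg or TrainConfig()
    rows = []
    for variant in variants:
        for seed in seeds:
            mcfg = replace(model_cfg, seed=seed)
            tcfg = replace(base_tcfg, seed=seed)
            model = make_variant(mcfg, variant)
            if not model.config.ud:
                tcfg = replace(tcfg, gamma=0.0)
            train(model, train_tiles, val_tiles, tcfg)
            res = evaluate(model, test_tiles)
            rows.append({"variant": variant, "seed": seed,
                         "accuracy": res["accuracy"], "f1": res["f1"],
                         "auc_roc": res.get("auc_roc", float("nan")),
                         "mean_ue_pearson": res["mean_ue_pearson"]})
    return rows


# ---------------------------------------------------------------------------
# config + checkpoint I/O
# ---------------------------------------------------------------------------

def load_config(path: str) -> tuple[ModelConfig, TrainConfig]:
    """YAML with optional `model:`, `train:` and `augment:` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mcfg = ModelConfig(**(raw.get("model") or {}))
    tkw = dict(raw.get("train") or {})
    akw = raw.get("augment")
    if akw is not None:
        if akw.get("crop_scale") is not None:
            akw["crop_scale"] = tuple(akw["crop_scale"])
        tkw["augment"] = AugmentParams(**akw)
    tcfg = TrainConfig(**tkw)
    return mcfg, tcfg


def save_checkpoint(model: Model, path: str,
                    train_config: TrainConfig | None = None,
                    record: RunRecord | None = None):
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    meta = {"model_config": dataclasses.asdict(model.config)}
    if train_config is not None:
        d = dataclasses.asdict(train_config)
        d["augment"] = dataclasses.asdict(train_config.augment)
        meta["train_config"] = d
    if record is not None:
        meta["best_epoch"] = record.best_epoch
        meta["best_val_f1"] = record.best_val_f1
    np.savez(path, __meta__=json.dumps(meta),
             **{f"p{k}": v for k, v in model.state_dict().items()})


def load_checkpoint(path: str) -> Model:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k[1:]: z[k] for k in z.files if k.startswith("p")}
    model = Model(ModelConfig(**meta["model_config"]))
    model.load_state_dict(state)
    return model
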