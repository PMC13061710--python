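"""Training objective (cross-entropy + uncertainty-calibration term) and
evaluation metrics.

The calibration term rewards agreement between the per-position
uncertainty map U and the per-position classification-error map
E = |local_prob - label|: with the default 'pearson' metric it is
1 - corr(U, E), bounded in [0, 2]; 'spearman' uses rank correlation
(value only, no gradient); 'mse' compares min-max-normalized maps.
All loss functions accept autograd tensors (differentiable) or NumPy
arrays (returning floats).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .autograd import Tensor

__all__ = [
    "LossBreakdown", "ConfusionCounts",
    "cross_entropy", "error_map", "ual_loss", "total_loss",
    "confusion", "accuracy", "precision", "recall", "f1_score", "auc_roc",
    "evaluate_predictions",
]

PROB_EPS = 1e-7
VAR_TOL = 1e-12


@dataclass
class LossBreakdown:
    cel: float
    ual: float
    gamma: float = 0.1

    @property
    def total(self) -> float:
        return self.cel + self.gamma * self.ual


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=float)), False


def cross_entropy(pred_prob, label, class_weights=None,
                  label_smoothing: float = 0.0):
    """Binary cross-entropy on the predicted abnormal probability.

    pred_prob: scalar or (N,) probabilities of the positive class;
    label: matching {0,1} values.  With label smoothing s the target
    becomes (1 - s) * y + s / 2.  class_weights, if given, maps each
    sample's weight by its true class: (w_class0, w_class1).
    Probabilities are clipped to [eps, 1 - eps]; natural log.
    """
    p, was_tensor = _as_tensor(pred_prob)
    y = np.atleast_1d(np.asarray(label, dtype=float))
    t = (1.0 - label_smoothing) * y + label_smoothing / 2.0
    if class_weights is None:
        w = np.ones_like(y)
    else:
        w = np.where(y > 0.5, class_weights[1], class_weights[0])
    pc = p.reshape(y.shape) if p.size == y.size else p
    pc = pc.clip(PROB_EPS, 1.0 - PROB_EPS)
    per = (pc.log() * (-t) - (1.0 - pc).log() * (1.0 - t)) * w
    out = per.mean()
    return out if was_tensor else float(out.item())


def error_map(local_prob, label):
    """E = |local_prob - label| elementwise against the scalar label."""
    p, was_tensor = _as_tensor(local_prob)
    if np.any(p.data < 0) or np.any(p.data > 1):
        raise ValueError("local probabilities must lie in [0, 1]")
    y = float(label)
    diff = p - y
    out = (diff * diff + 1e-30).sqrt() if was_tensor else None
    if was_tensor:
        return out
    return np.abs(p.data - y)


def _pearson_loss_t(u: Tensor, e: Tensor) -> tuple[Tensor, bool]:
    """1 - Pearson corr over all positions; flags zero-variance input."""
    n = u.size
    uc = u - u.mean()
    ec = e - e.mean()
    vu = (uc * uc).sum() * (1.0 / n)
    ve = (ec * ec).sum() * (1.0 / n)
    degenerate = float(vu.item()) < VAR_TOL or float(ve.item()) < VAR_TOL
    if degenerate:
        return Tensor(np.asarray(1.0)), True
    cov = (uc * ec).sum() * (1.0 / n)
    rho = cov / ((vu * ve).sqrt() + 1e-12)
    return 1.0 - rho, False


def ual_loss(u, e, metric: str = "pearson"):
    """Uncertainty-calibration loss for one sample (maps of equal shape).

    pearson: 1 - corr(U, E) in [0, 2]; spearman: 1 - rank-corr (value
    only -- ranks are piecewise constant so no gradient flows); mse:
    mean squared difference of min-max-normalized maps.  Samples where
    either map has zero variance contribute the neutral value 1
    (pearson/spearman).
    """
    ut, u_tensor = _as_tensor(u)
    et, e_tensor = _as_tensor(e)
    was_tensor = u_tensor or e_tensor
    if ut.shape != et.shape:
        raise ValueError(f"shape mismatch {ut.shape} vs {et.shape}")
    if metric == "pearson":
        out, _ = _pearson_loss_t(ut, et)
    elif metric == "spearman":
        ur = rankdata(ut.data.ravel()).reshape(ut.shape)
        er = rankdata(et.data.ravel()).reshape(et.shape)
        out, _ = _pearson_loss_t(Tensor(ur), Tensor(er))
    elif metric == "mse":
        out = _mse_norm_t(ut, et)
    else:
        raise ValueError(f"unknown UAL metric {metric!r}")
    return out if was_tensor else float(out.item())


def _minmax_t(x: Tensor) -> Tensor:
    lo = float(x.data.min())
    hi = float(x.data.max())
    return (x - lo) * (1.0 / max(hi - lo, 1e-12))


def _mse_norm_t(u: Tensor, e: Tensor) -> Tensor:
    d = _minmax_t(u) - _minmax_t(e)
    return (d * d).mean()


def ual_loss_batch(u: Tensor, e: Tensor, metric: str = "pearson") -> Tensor:
    """Per-sample UAL averaged over the batch (leading axis)."""
    losses = [ual_loss(u[i], e[i], metric) for i in range(u.shape[0])]
    total = losses[0]
    for term in losses[1:]:
        total = total + term
    return total * (1.0 / len(losses))


def total_loss(cel: float, ual: float, gamma: float = 0.1) -> LossBreakdown:
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return LossBreakdown(cel=float(cel), ual=float(ual), gamma=float(gamma))


# ---------------------------------------------------------------------------
# evaluation metrics (abnormal = positive class)
# ---------------------------------------------------------------------------

def confusion(pred_labels, true_labels) -> ConfusionCounts:
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


def _ratio(num: float, den: float) -> float:
    """Zero-denominator ratios return 0 rather than raising."""
    return num / den if den > 0 else 0.0


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def f1_score(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    return _ratio(2.0 * p * r, p + r)


def auc_roc(scores, labels) -> float:
    """Rank-based AUC: probability a random positive outscores a random
    negative, ties counted half (normalized Mann-Whitney U)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_predictions(scores, true_labels, threshold: float = 0.5) -> dict:
    """Standard metric bundle from abnormal-probability scores."""
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true_labels, dtype=int)
    c = confusion((scores >= threshold).astype(int), true)
    out = {
        "accuracy": accuracy(c),
        "precision": precision(c),
        "recall": recall(c),
        "f1": f1_score(c),
        "confusion": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
    }
    if 0 < true.sum() < true.size:
        out["auc_roc"] = auc_roc(scores, true)
    return out
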