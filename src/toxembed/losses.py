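"""Imbalance-aware loss family for sparse multitask binary labels.

The primary objective is a weighted focal loss

    L = mean over observed (n, p) of
        w+_p * (1 - s)^gamma * y * (-log s)  +  s^gamma * (1 - y) * (-log(1 - s))

with s = sigmoid(f_np), per-task positive weights

    w+_p = alpha * N_p- / N_p+ + (1 - alpha),        alpha in [0, 1]

and focusing exponent gamma >= 0.  It reduces exactly to focal loss at
alpha = 0, to class-weighted BCE at gamma = 0, and to plain BCE at
alpha = gamma = 0.  Missing labels (NaN) contribute neither loss nor
weight counts.  Log-probabilities are computed through the numerically
stable log-sigmoid; probabilities are never clipped.

Also here: the masked-token cross-entropy and descriptor-regression MSE
used in pretraining, and the per-class log-loss diagnostic used to expose
majority-class bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .labels import SparseLabelMatrix


@dataclass
class LossConfig:
    """Configuration of the weighted focal loss family.

    ``alpha`` interpolates the positive weight between 1 (alpha=0) and the
    inverse class ratio (alpha=1); ``gamma`` is the focusing exponent.
    Per-task weights may be supplied directly; otherwise they are derived
    from observed label counts via :func:`positive_weights`.
    """

    alpha: float = 0.0
    gamma: float = 0.0
    reduction: str = "mean"  # "mean" over observed entries, or "sum"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def positive_weights(
    n_pos: np.ndarray, n_neg: np.ndarray, alpha: float
) -> np.ndarray:
    """Per-task positive weights  w+_p = alpha * N-/N+ + (1 - alpha).

    Tasks with no observed positives get weight NaN and a warning: the
    inverse ratio is undefined there and such tasks should be excluded
    (or filtered upstream).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n_pos = np.asarray(n_pos, dtype=np.float64)
    n_neg = np.asarray(n_neg, dtype=np.float64)
    out = np.full(n_pos.shape, np.nan)
    ok = n_pos > 0
    out[ok] = alpha * n_neg[ok] / n_pos[ok] + (1.0 - alpha)
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} task(s) have no observed positives; "
            "their positive weight is undefined",
            stacklevel=2,
        )
    return out


def _log_sigmoid(f: np.ndarray) -> np.ndarray:
    """log(sigmoid(f)) without overflow: -softplus(-f)."""
    return np.where(f >= 0, -np.log1p(np.exp(-np.abs(f))), f - np.log1p(np.exp(-np.abs(f))))


def _sigmoid(f: np.ndarray) -> np.ndarray:
    out = np.empty_like(f, dtype=np.float64)
    pos = f >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-f[pos]))
    e = np.exp(f[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _as_label_array(y: SparseLabelMatrix | np.ndarray) -> np.ndarray:
    if isinstance(y, SparseLabelMatrix):
        return y.values
    return np.asarray(y, dtype=np.float64)


def weighted_focal_loss(
    y: SparseLabelMatrix | np.ndarray,
    f: np.ndarray,
    cfg: LossConfig,
) -> float:
    """Weighted focal loss over observed entries of a sparse label matrix.

    ``f`` holds raw logits aligned with ``y``; NaN labels are skipped.
    The default reduction is the mean over observed entries, which keeps
    the magnitude batch-size invariant; ``reduction="sum"`` gives the raw
    double sum.
    """
    y_arr = _as_label_array(y)
    f = np.asarray(f, dtype=np.float64)
    if y_arr.shape != f.shape:
        raise ValueError(f"shape mismatch: labels {y_arr.shape} vs logits {f.shape}")
    if np.any(np.isnan(f)):
        raise ValueError("logits contain NaN")
    obs = ~np.isnan(y_arr)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("all labels are missing")

    if cfg.weights is not None:
        w = np.asarray(cfg.weights, dtype=np.float64)
    else:
        yy = np.where(obs, y_arr, 0.0)
        n_pos = yy.sum(axis=0)
        n_neg = obs.sum(axis=0) - n_pos
        w = np.ones(y_arr.shape[1])
        has_pos = n_pos > 0
        w[has_pos] = cfg.alpha * n_neg[has_pos] / n_pos[has_pos] + (1.0 - cfg.alpha)
    if w.shape != (y_arr.shape[1],):
        raise ValueError("weights must have one entry per task")

    log_s = _log_sigmoid(f)
    log_1ms = _log_sigmoid(-f)
    s = _sigmoid(f)
    y0 = np.where(obs, y_arr, 0.0)
    per_entry = (
        w[None, :] * (1.0 - s) ** cfg.gamma * y0 * (-log_s)
        + s ** cfg.gamma * (1.0 - y0) * (-log_1ms)
    )
    total = float(per_entry[obs].sum())
    return total / n_obs if cfg.reduction == "mean" else total


def bce_loss(y: SparseLabelMatrix | np.ndarray, f: np.ndarray,
             reduction: str = "mean") -> float:
    """Plain binary cross-entropy: the alpha = gamma = 0 member of the family."""
    return weighted_focal_loss(y, f, LossConfig(0.0, 0.0, reduction))


def masking_loss(
    pred_logits: np.ndarray, true_tokens: np.ndarray, mask: np.ndarray
) -> float:
    """Mean softmax cross-entropy over masked positions.

    ``pred_logits`` is (T, V) or (B, T, V); ``mask`` marks the corrupted
    positions.  Unmasked positions contribute exactly zero; with no masked
    position the mean is undefined and this raises.
    """
    logits = np.asarray(pred_logits, dtype=np.float64)
    tokens = np.asarray(true_tokens, dtype=np.int64)
    m = np.asarray(mask, dtype=bool)
    if logits.ndim == 2:
        logits, tokens, m = logits[None], tokens[None], m[None]
    n_masked = int(m.sum())
    if n_masked == 0:
        raise ValueError("no masked positions: masking loss undefined")
    zmax = logits.max(axis=-1, keepdims=True)
    lse = zmax[..., 0] + np.log(np.exp(logits - zmax).sum(axis=-1))
    true_logit = np.take_along_axis(logits, tokens[..., None], axis=-1)[..., 0]
    nll = lse - true_logit
    return float(nll[m].sum() / n_masked)


def physchem_loss(estimates: np.ndarray, targets: np.ndarray) -> float:
    """Descriptor-regression MSE: mean over samples of the squared
    Euclidean distance summed across properties."""
    est = np.asarray(estimates, dtype=np.float64)
    tgt = np.asarray(targets, dtype=np.float64)
    if est.shape != tgt.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {tgt.shape}")
    if est.ndim == 1:
        est, tgt = est[None], tgt[None]
    if est.shape[0] == 0:
        raise ValueError("empty batch")
    return float(((est - tgt) ** 2).sum(axis=1).mean())


@dataclass
class ClasswiseLoss:
    """Per-task mean log-loss of positives and negatives (both >= 0).

    A side with no observed instances is reported as NaN, never as 0.
    """

    task_names: list[str]
    loss_pos: np.ndarray
    loss_neg: np.ndarray
    n_pos: np.ndarray
    n_neg: np.ndarray

    @property
    def gap(self) -> np.ndarray:
        return self.loss_pos - self.loss_neg


def classwise_logloss(
    y: SparseLabelMatrix | np.ndarray,
    f: np.ndarray,
    task_names: list[str] | None = None,
) -> ClasswiseLoss:
    """Per-class log-loss diagnostic.

    L_pos(p) = mean over observed positives of -log sigmoid(f);
    L_neg(p) = mean over observed negatives of -log(1 - sigmoid(f)).
    A wide positive-minus-negative gap signals majority-class bias.
    """
    y_arr = _as_label_array(y)
    f = np.asarray(f, dtype=np.float64)
    if y_arr.shape != f.shape:
        raise ValueError("shape mismatch between labels and logits")
    if task_names is None:
        task_names = (
            list(y.task_names)
            if isinstance(y, SparseLabelMatrix)
            else [f"task_{j}" for j in range(y_arr.shape[1])]
        )
    obs = ~np.isnan(y_arr)
    pos = obs & (y_arr == 1.0)
    neg = obs & (y_arr == 0.0)
    nll_pos = -_log_sigmoid(f)
    nll_neg = -_log_sigmoid(-f)
    n_pos = pos.sum(axis=0)
    n_neg = neg.sum(axis=0)
    with np.errstate(invalid="ignore"):
        loss_pos = np.where(n_pos > 0,
                            np.where(pos, nll_pos, 0.0).sum(axis=0) / np.maximum(n_pos, 1),
                            np.nan)
        loss_neg = np.where(n_neg > 0,
                            np.where(neg, nll_neg, 0.0).sum(axis=0) / np.maximum(n_neg, 1),
                            np.nan)
    return ClasswiseLoss(task_names, loss_pos, loss_neg, n_pos, n_neg)
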