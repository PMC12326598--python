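"""Precision-recall-first evaluation and imbalance diagnostics.

AUPR is computed as the area under the step-wise precision envelope over
recall (interpolated precision max'ed over higher recalls), ROC-AUC by the
trapezoid rule, and MCC at a fixed 0.5 threshold.  Tasks with a single
observed class are flagged rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from .labels import SparseLabelMatrix
from .losses import classwise_logloss


def aupr(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision envelope over recall.

    Uses the step-wise interpolated precision p_interp(r) = max over
    recall >= r of precision, integrated across distinct score cuts.
    """
    y = np.asarray(y_true, dtype=np.float64)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must align")
    n_pos = y.sum()
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("AUPR undefined for a single-class task")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    ranks = np.arange(1, y.size + 1)
    # evaluate only at the last index of each tied score block
    block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, ranks = tp[block_end], ranks[block_end]
    precision = tp / ranks
    recall = tp / n_pos
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    dr = np.diff(np.r_[0.0, recall])
    return float((dr * envelope).sum())


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoid-rule ROC-AUC."""
    return float(roc_auc_score(y_true, scores))


def mcc_at_half(y_true: np.ndarray, probs: np.ndarray) -> float:
    """Matthews correlation coefficient with predictions thresholded at 0.5."""
    return float(matthews_corrcoef(y_true.astype(int), (probs >= 0.5).astype(int)))


@dataclass
class MetricReport:
    """Per-task metric table; single-class tasks appear in ``flagged``."""

    table: pd.DataFrame  # columns: task, aupr, roc_auc, mcc, positive_ratio, n_pos, n_neg
    flagged: list[str]

    def mean(self, metric: str = "aupr") -> float:
        return float(self.table[metric].mean())


def compute_metrics(
    y: SparseLabelMatrix | np.ndarray,
    probs: np.ndarray,
    task_names: list[str] | None = None,
) -> MetricReport:
    """Per-task AUPR / ROC-AUC / MCC over observed labels only."""
    values = y.values if isinstance(y, SparseLabelMatrix) else np.asarray(y, dtype=float)
    if task_names is None:
        task_names = (
            list(y.task_names) if isinstance(y, SparseLabelMatrix)
            else [f"task_{j}" for j in range(values.shape[1])]
        )
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != values.shape:
        raise ValueError("probability matrix must align with labels")
    rows, flagged = [], []
    for j, name in enumerate(task_names):
        obs = ~np.isnan(values[:, j])
        yj = values[obs, j]
        pj = probs[obs, j]
        n_pos = int(yj.sum())
        n_neg = int(obs.sum() - n_pos)
        if n_pos == 0 or n_neg == 0 or np.any(np.isnan(pj)):
            flagged.append(name)
            rows.append((name, np.nan, np.nan, np.nan,
                         np.nan if n_pos + n_neg == 0 else n_pos / (n_pos + n_neg),
                         n_pos, n_neg))
            continue
        rows.append((
            name,
            aupr(yj, pj),
            roc_auc(yj, pj),
            mcc_at_half(yj, pj),
            n_pos / (n_pos + n_neg),
            n_pos,
            n_neg,
        ))
    table = pd.DataFrame(
        rows, columns=["task", "aupr", "roc_auc", "mcc", "positive_ratio", "n_pos", "n_neg"]
    )
    return MetricReport(table=table, flagged=flagged)


@dataclass
class ImbalanceSensitivity:
    """Spearman correlation between per-task AUPR and positive ratio."""

    rho: float
    p_value: float
    slope: float
    intercept: float
    table: pd.DataFrame
    degenerate: bool = False


def imbalance_sensitivity(report: MetricReport) -> ImbalanceSensitivity:
    """How strongly performance tracks class balance across tasks.

    A high positive rank correlation means the model does well only where
    positives are plentiful — the signature of imbalance sensitivity.
    """
    table = report.table.dropna(subset=["aupr", "positive_ratio"])
    if len(table) < 3:
        raise ValueError("need at least 3 scored tasks for a rank correlation")
    x = table["positive_ratio"].to_numpy()
    y = table["aupr"].to_numpy()
    degenerate = bool(np.all(y == y[0]) or np.all(x == x[0]))
    if degenerate:
        rho, p = np.nan, np.nan
    else:
        rho, p = stats.spearmanr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return ImbalanceSensitivity(
        rho=float(rho), p_value=float(p), slope=float(slope),
        intercept=float(intercept),
        table=table[["task", "aupr", "positive_ratio"]].reset_index(drop=True),
        degenerate=degenerate,
    )


@dataclass
class LoglossGapReport:
    """Per-task positive/negative log-losses and a dispersion-ellipse summary."""

    table: pd.DataFrame  # columns: task, loss_pos, loss_neg, gap
    center: tuple[float, float]
    covariance: np.ndarray
    ellipse_axes: tuple[float, float]  # 95% covariance-ellipse semi-axes
    ellipse_angle_deg: float


def _probs_to_logits(probs: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    p = np.clip(np.asarray(probs, dtype=np.float64), eps, 1.0 - eps)
    return np.log(p) - np.log1p(-p)


def logloss_gap_report(
    y: SparseLabelMatrix | np.ndarray,
    probs: np.ndarray,
    task_names: list[str] | None = None,
) -> LoglossGapReport:
    """Tabulate per-class log-losses and summarize their spread.

    The ellipse is the 95% covariance ellipse of the per-task
    (L_neg, L_pos) points; a wide vertical offset from the diagonal means
    the model is biased toward the negative (majority) class.
    """
    cw = classwise_logloss(y, _probs_to_logits(probs), task_names)
    table = pd.DataFrame(
        {
            "task": cw.task_names,
            "loss_pos": cw.loss_pos,
            "loss_neg": cw.loss_neg,
            "gap": cw.gap,
        }
    )
    pts = table.dropna(subset=["loss_pos", "loss_neg"])[["loss_neg", "loss_pos"]].to_numpy()
    if len(pts) == 0:
        raise ValueError("no task has both classes observed")
    center = pts.mean(axis=0)
    if len(pts) > 1:
        cov = np.cov(pts.T)
    else:
        cov = np.zeros((2, 2))
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    chi2_95 = stats.chi2.ppf(0.95, df=2)
    axes = tuple(float(np.sqrt(max(v, 0.0) * chi2_95)) for v in evals[::-1])
    major = evecs[:, np.argmax(evals)]
    angle = float(np.degrees(np.arctan2(major[1], major[0])))
    return LoglossGapReport(
        table=table,
        center=(float(center[0]), float(center[1])),
        covariance=np.atleast_2d(cov),
        ellipse_axes=axes,
        ellipse_angle_deg=angle,
    )


# ---------------------------------------------------------------------------
# Optional figure helpers
# ---------------------------------------------------------------------------


def plot_logloss_gap(report: LoglossGapReport, path: str) -> None:
    """Scatter of per-task (L_neg, L_pos) with the 95% covariance ellipse."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(4, 4))
    pts = report.table.dropna(subset=["loss_pos", "loss_neg"])
    ax.scatter(pts["loss_neg"], pts["loss_pos"], s=18, alpha=0.7)
    ax.add_patch(
        Ellipse(
            report.center,
            2 * report.ellipse_axes[0],
            2 * report.ellipse_axes[1],
            angle=report.ellipse_angle_deg,
            fill=False,
            color="tab:red",
        )
    )
    lim = max(ax.get_xlim()[1], ax.get_ylim()[1])
    ax.plot([0, lim], [0, lim], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("negative log-loss")
    ax.set_ylabel("positive log-loss")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_imbalance_sensitivity(sens: ImbalanceSensitivity, path: str) -> None:
    """AUPR vs positive ratio with the fitted regression line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    x = sens.table["positive_ratio"]
    ax.scatter(x, sens.table["aupr"], s=18, alpha=0.7)
    xs = np.linspace(float(x.min()), float(x.max()), 50)
    ax.plot(xs, sens.slope * xs + sens.intercept, c="tab:red", lw=1)
    ax.set_xlabel("positive ratio")
    ax.set_ylabel("AUPR")
    ax.set_title(f"Spearman rho = {sens.rho:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
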