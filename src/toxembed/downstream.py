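"""Frozen-encoder probing of in vivo endpoints.

The pretrained encoder is never updated here: molecules are embedded once
(deterministically), and a small skip-connected multitask MLP head is
trained on the embeddings with the weighted-focal-loss family.  Loss
hyperparameters (alpha, gamma) and regularizers are selected by inner
cross-validation on the non-test scaffold folds, scored by mean
validation AUPR; the scaffold test fold is never touched until the final
report.  Fingerprint-based Random Forest and multitask MLP baselines
share the identical split protocol and metric schema.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import chem
from .chem import Molecule, SplitAssignment, Vocab
from .evaluation import MetricReport, aupr, compute_metrics
from .labels import SparseLabelMatrix
from .nn import Adam, BatchNorm1d, Linear, Module
from .nn import autograd as ag
from .nn.autograd import Tensor
from .pretrain import PretrainModel, collate, focal_loss_tensor, load_checkpoint


# ---------------------------------------------------------------------------
# Embedding extraction
# ---------------------------------------------------------------------------


def extract_embeddings(
    mols: list[Molecule],
    model: PretrainModel | str | Path,
    vocab: Vocab | None = None,
    batch_size: int = 64,
) -> np.ndarray:
    """Pooled clean-pass embeddings (N, H) from a frozen encoder.

    ``model`` may be a loaded :class:`PretrainModel` (with ``vocab``) or a
    checkpoint path.  The encoder runs in eval mode and its weights are
    left untouched.
    """
    if not isinstance(model, PretrainModel):
        model, vocab = load_checkpoint(model)
    if vocab is None:
        raise ValueError("vocab required alongside a bare model")
    max_length = model.encoder_config.max_length
    seqs = []
    for mol in mols:
        try:
            seqs.append(chem.tokenize(mol, vocab, max_length))
        except ValueError as err:
            raise ValueError(
                f"molecule {mol.canonical_smiles!r} exceeds max_length {max_length}"
            ) from err
    model.eval()
    rng = np.random.default_rng(0)  # dropout disabled in eval; rng unused
    out = np.empty((len(mols), model.encoder_config.hidden))
    for start in range(0, len(mols), batch_size):
        batch = seqs[start : start + batch_size]
        ids, pad_mask = collate(batch, vocab, max_length)
        hidden = model.encoder(ids, pad_mask, rng)
        out[start : start + len(batch)] = model.encoder.pooled(hidden, pad_mask).data
    return out


# ---------------------------------------------------------------------------
# Skip-connected multitask MLP head
# ---------------------------------------------------------------------------


class SkipMLP(Module):
    """input -> hidden (batch norm, ReLU, dropout) -> [input ++ hidden] -> logits."""

    def __init__(self, n_in: int, n_tasks: int, hidden: int, dropout: float, seed: int):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.n_in = n_in
        self.dropout = dropout
        self.fc1 = Linear(n_in, hidden, rng, init_scale=np.sqrt(2.0 / n_in))
        self.bn = BatchNorm1d(hidden)
        self.out = Linear(n_in + hidden, n_tasks, rng, init_scale=np.sqrt(1.0 / (n_in + hidden)))
        self._rng = np.random.default_rng(seed + 1)

    def logits(self, x: np.ndarray | Tensor) -> Tensor:
        x = ag.as_tensor(x)
        if x.shape[1] != self.n_in:
            raise ValueError(f"input width {x.shape[1]} != expected {self.n_in}")
        h = ag.relu(self.bn(self.fc1(x)))
        h = ag.dropout(h, self.dropout, self._rng, self.training)
        merged = ag.concat([x, h], axis=1)
        return self.out(merged)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-task probabilities in (0, 1); deterministic in eval mode."""
        was_training = self.training
        self.eval()
        probs = ag.sigmoid(self.logits(x)).data
        if was_training:
            self.train()
        return probs


@dataclass
class MLPHeadConfig:
    """Head geometry, optimization schedule and hyperparameter grids."""

    hidden: int = 128
    dropout: float = 0.1
    loss_grid: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 0.0), (1.0, 0.0), (0.0, 2.0), (1.0, 2.0)]
    )
    weight_decay_grid: list[float] = field(default_factory=lambda: [0.0])
    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    patience: int = 10
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.loss_grid or not self.weight_decay_grid:
            raise ValueError("hyperparameter grids must be non-empty")


def _positive_weights(labels: np.ndarray, alpha: float) -> np.ndarray:
    obs = ~np.isnan(labels)
    n_pos = np.nansum(labels, axis=0)
    n_neg = obs.sum(axis=0) - n_pos
    w = np.ones(labels.shape[1])
    ok = n_pos > 0
    w[ok] = alpha * n_neg[ok] / n_pos[ok] + (1 - alpha)
    return w


def _macro_aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    vals = []
    for j in range(labels.shape[1]):
        obs = ~np.isnan(labels[:, j])
        yj = labels[obs, j]
        if yj.size and 0 < yj.sum() < yj.size:
            vals.append(aupr(yj, scores[obs, j]))
    return float(np.mean(vals)) if vals else np.nan


def train_mlp(
    x_train: np.ndarray,
    y_train: np.ndarray,
    alpha: float,
    gamma: float,
    weight_decay: float,
    cfg: MLPHeadConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    epochs: int | None = None,
) -> tuple[SkipMLP, float, int]:
    """Train one multitask head; returns (model, best val AUPR, best epoch).

    With a validation set, training early-stops on validation AUPR with
    the configured patience and restores the best weights.  Without one,
    it runs for the requested number of epochs and returns NaN AUPR.
    """
    n, d = x_train.shape
    model = SkipMLP(d, y_train.shape[1], cfg.hidden, cfg.dropout, cfg.seed)
    weights = _positive_weights(y_train, alpha)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=weight_decay)
    rng = np.random.default_rng(cfg.seed + 7)
    n_epochs = epochs or cfg.epochs
    best_score, best_epoch, best_state = -np.inf, 0, None
    stale = 0
    for epoch in range(n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            rows = order[start : start + cfg.batch_size]
            yb = y_train[rows]
            if np.all(np.isnan(yb)):
                continue
            logits = model.logits(x_train[rows])
            loss = focal_loss_tensor(logits, yb, weights, gamma)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"head training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
        if x_val is not None:
            score = _macro_aupr(y_val, model.predict_proba(x_val))
            if np.isnan(score):
                raise ValueError(
                    "validation fold has no task with both classes observed; "
                    "review the stratification of the split"
                )
            if score > best_score:
                best_score, best_epoch = score, epoch
                best_state = model.state_dict()
                best_state = {k: v.copy() for k, v in best_state.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
        return model, best_score, best_epoch + 1
    return model, np.nan, n_epochs


# ---------------------------------------------------------------------------
# Cross-validated fitting
# ---------------------------------------------------------------------------


@dataclass
class DownstreamReport:
    """Result of the frozen-feature protocol on one feature matrix."""

    model: SkipMLP | None
    best_params: dict
    cv_table: pd.DataFrame  # one row per grid point with mean inner-val AUPR
    test_report: MetricReport
    test_probs: np.ndarray


def _inner_folds(idx: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(idx)
    return [shuffled[i::k] for i in range(k)]


def _check_fold_positives(y: np.ndarray, folds: list[np.ndarray]) -> None:
    for i, fold in enumerate(folds):
        block = y[fold]
        if np.nansum(block) == 0:
            raise ValueError(
                f"inner CV fold {i} contains zero positives for every task; "
                "review the stratification of the split"
            )


def fit_downstream(
    x: np.ndarray,
    y: SparseLabelMatrix,
    split: SplitAssignment,
    cfg: MLPHeadConfig | None = None,
) -> DownstreamReport:
    """Grid-search (alpha, gamma, weight decay) by inner CV, then test once.

    The scaffold test fold is held out before any tuning; selection is by
    mean inner-validation AUPR, the winning setting is retrained on all
    non-test data, and per-task test metrics are reported.
    """
    cfg = cfg or MLPHeadConfig()
    x = np.asarray(x, dtype=np.float64)
    test_idx = split.test_indices()
    dev_idx = split.train_indices()
    folds = _inner_folds(dev_idx, cfg.inner_folds, cfg.seed)
    _check_fold_positives(y.values, folds)

    rows = []
    best = None
    for alpha, gamma in cfg.loss_grid:
        for wd in cfg.weight_decay_grid:
            scores, epochs_used = [], []
            for i, fold in enumerate(folds):
                tr = np.concatenate([f for j, f in enumerate(folds) if j != i])
                _, score, n_ep = train_mlp(
                    x[tr], y.values[tr], alpha, gamma, wd, cfg,
                    x_val=x[fold], y_val=y.values[fold],
                )
                scores.append(score)
                epochs_used.append(n_ep)
            mean_score = float(np.mean(scores))
            rows.append({
                "alpha": alpha, "gamma": gamma, "weight_decay": wd,
                "mean_val_aupr": mean_score,
            })
            if best is None or mean_score > best["mean_val_aupr"]:
                best = {
                    "alpha": alpha, "gamma": gamma, "weight_decay": wd,
                    "mean_val_aupr": mean_score,
                    "epochs": int(np.ceil(np.mean(epochs_used))),
                }
    cv_table = pd.DataFrame(rows)

    final, _, _ = train_mlp(
        x[dev_idx], y.values[dev_idx],
        best["alpha"], best["gamma"], best["weight_decay"], cfg,
        epochs=best["epochs"],
    )
    test_probs = final.predict_proba(x[test_idx])
    test_report = compute_metrics(y.select_molecules(test_idx), test_probs)
    return DownstreamReport(
        model=final, best_params=best, cv_table=cv_table,
        test_report=test_report, test_probs=test_probs,
    )


# ---------------------------------------------------------------------------
# Baselines: Random Forest per task + multitask MLP on fingerprints
# ---------------------------------------------------------------------------


@dataclass
class BaselineReport:
    rf: MetricReport
    mlp: DownstreamReport
    rf_params: dict[str, dict]


def fit_baselines(
    fingerprints: np.ndarray,
    y: SparseLabelMatrix,
    split: SplitAssignment,
    cfg: MLPHeadConfig | None = None,
    rf_grid: list[dict] | None = None,
) -> BaselineReport:
    """Tree-ensemble and fingerprint-MLP baselines under the same protocol.

    Random Forests are fitted one per task with task-specific settings
    chosen by inner-CV AUPR; the multitask MLP reuses
    :func:`fit_downstream` on the fingerprint matrix.
    """
    cfg = cfg or MLPHeadConfig()
    rf_grid = rf_grid or [
        {"n_estimators": 200, "max_depth": None},
        {"n_estimators": 200, "max_depth": 8},
    ]
    x = np.asarray(fingerprints, dtype=np.float64)
    test_idx = split.test_indices()
    dev_idx = split.train_indices()
    folds = _inner_folds(dev_idx, cfg.inner_folds, cfg.seed)

    test_probs = np.full((len(test_idx), y.n_tasks), np.nan)
    chosen: dict[str, dict] = {}
    for j, task in enumerate(y.task_names):
        yj = y.values[:, j]
        obs_dev = dev_idx[~np.isnan(yj[dev_idx])]
        if obs_dev.size == 0 or np.nansum(yj[obs_dev]) in (0, obs_dev.size):
            continue
        best_params, best_score = None, -np.inf
        for params in rf_grid:
            scores = []
            for i, fold in enumerate(folds):
                tr = np.concatenate([f for k, f in enumerate(folds) if k != i])
                tr = tr[~np.isnan(yj[tr])]
                va = fold[~np.isnan(yj[fold])]
                if tr.size == 0 or va.size == 0:
                    continue
                if yj[tr].sum() in (0, tr.size) or yj[va].sum() in (0, va.size):
                    continue
                clf = RandomForestClassifier(random_state=cfg.seed, n_jobs=1, **params)
                clf.fit(x[tr], yj[tr].astype(int))
                scores.append(aupr(yj[va], clf.predict_proba(x[va])[:, 1]))
            score = float(np.mean(scores)) if scores else -np.inf
            if score > best_score:
                best_score, best_params = score, params
        chosen[task] = best_params or rf_grid[0]
        clf = RandomForestClassifier(random_state=cfg.seed, n_jobs=1, **chosen[task])
        clf.fit(x[obs_dev], yj[obs_dev].astype(int))
        test_probs[:, j] = clf.predict_proba(x[test_idx])[:, 1]

    rf_report = compute_metrics(y.select_molecules(test_idx), test_probs)
    mlp_report = fit_downstream(x, y, split, cfg)
    return BaselineReport(rf=rf_report, mlp=mlp_report, rf_params=chosen)
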