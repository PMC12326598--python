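"""Binary task-matrix construction from potencies, readouts and severities.

Assay panels are sparse: most molecules are measured against a handful of
tasks.  Missing entries are first-class here — a label matrix stores
{0, 1, NaN} and every count, filter and loss downstream operates on the
observed entries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml


@dataclass
class SparseLabelMatrix:
    """Molecules x tasks binary labels with missing entries encoded as NaN."""

    values: np.ndarray  # N x P float array with entries in {0.0, 1.0, nan}
    task_names: list[str]
    molecule_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("label matrix must be 2-D")
        if self.values.shape[1] != len(self.task_names):
            raise ValueError("task_names length must match number of columns")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and not np.all(np.isin(observed, (0.0, 1.0))):
            raise ValueError("observed labels must be 0 or 1")

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of measured entries."""
        return ~np.isnan(self.values)

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-task (N_pos, N_neg) over observed entries."""
        obs = self.observed
        n_pos = np.nansum(self.values, axis=0).astype(int)
        n_neg = obs.sum(axis=0) - n_pos
        return n_pos, n_neg

    def positive_ratio(self) -> np.ndarray:
        n_pos, n_neg = self.counts()
        total = n_pos + n_neg
        with np.errstate(invalid="ignore"):
            return np.where(total > 0, n_pos / np.maximum(total, 1), np.nan)

    def select_tasks(self, idx: Sequence[int]) -> "SparseLabelMatrix":
        idx = list(idx)
        return SparseLabelMatrix(
            self.values[:, idx],
            [self.task_names[i] for i in idx],
            self.molecule_ids,
        )

    def select_molecules(self, idx: Sequence[int]) -> "SparseLabelMatrix":
        idx = np.asarray(idx)
        ids = None
        if self.molecule_ids is not None:
            ids = [self.molecule_ids[i] for i in idx]
        return SparseLabelMatrix(self.values[idx], list(self.task_names), ids)

    # -- I/O: CSV with an identifier column, empty cell = missing ----------

    def to_csv(self, path: str | Path, id_column: str = "molecule") -> None:
        ids = self.molecule_ids or [str(i) for i in range(self.n_molecules)]
        df = pd.DataFrame(self.values, columns=self.task_names)
        df.insert(0, id_column, ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, id_column: str = "molecule") -> "SparseLabelMatrix":
        df = pd.read_csv(path)
        if id_column not in df.columns:
            raise ValueError(f"identifier column {id_column!r} missing")
        ids = df[id_column].astype(str).tolist()
        tasks = [c for c in df.columns if c != id_column]
        return cls(df[tasks].to_numpy(dtype=np.float64), tasks, ids)


@dataclass
class EndpointStudy:
    """Dose/time-indexed endpoint records with per-endpoint expert thresholds.

    ``records`` is a long-format table with columns
    (molecule, endpoint, dose, time, value); ``value`` is a continuous
    readout (e.g. fold-of-control ALT elevation) for biochemistry or an
    ordinal severity grade for histopathology.
    """

    records: pd.DataFrame
    thresholds: dict[str, float] = field(default_factory=dict)

    REQUIRED = ("molecule", "endpoint", "dose", "time", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")

    @classmethod
    def from_csv(cls, path: str | Path, thresholds: dict[str, float] | None = None) -> "EndpointStudy":
        return cls(pd.read_csv(path), thresholds or {})

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @property
    def endpoints(self) -> list[str]:
        return sorted(self.records["endpoint"].unique())

    @property
    def molecules(self) -> list[str]:
        return list(dict.fromkeys(self.records["molecule"].astype(str)))


def default_biochemistry_thresholds() -> dict[str, float]:
    """Ship-with defaults: fold-of-control elevation factors per readout."""
    text = resources.files("toxembed.data").joinpath("biochem_thresholds.yaml").read_text()
    return {str(k): float(v) for k, v in yaml.safe_load(text).items()}


# ---------------------------------------------------------------------------
# Potency binarization
# ---------------------------------------------------------------------------


def ic50_to_pic50(ic50_molar: float | np.ndarray) -> float | np.ndarray:
    """pIC50 = -log10(IC50 in mol/L); higher means more potent."""
    arr = np.asarray(ic50_molar, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be a positive concentration in mol/L")
    out = -np.log10(arr)
    return float(out) if np.isscalar(ic50_molar) or out.ndim == 0 else out


def binarize_potency(
    pic50: pd.DataFrame | np.ndarray,
    threshold: float,
    task_names: Sequence[str] | None = None,
    molecule_ids: Sequence[str] | None = None,
) -> SparseLabelMatrix:
    """Active iff pIC50 strictly exceeds the threshold; NaN stays missing."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if isinstance(pic50, pd.DataFrame):
        task_names = list(pic50.columns)
        molecule_ids = [str(i) for i in pic50.index]
        arr = pic50.to_numpy(dtype=np.float64)
    else:
        arr = np.asarray(pic50, dtype=np.float64)
        if task_names is None:
            task_names = [f"task_{j}" for j in range(arr.shape[1])]
    values = np.where(np.isnan(arr), np.nan, (arr > threshold).astype(np.float64))
    return SparseLabelMatrix(values, list(task_names),
                             list(molecule_ids) if molecule_ids is not None else None)


def filter_tasks(
    m: SparseLabelMatrix, min_pos: int, min_neg: int
) -> SparseLabelMatrix:
    """Keep tasks with at least ``min_pos`` positives and ``min_neg`` negatives."""
    if min_pos < 0 or min_neg < 0:
        raise ValueError("minimum counts must be non-negative")
    n_pos, n_neg = m.counts()
    keep = [j for j in range(m.n_tasks) if n_pos[j] >= min_pos and n_neg[j] >= min_neg]
    if not keep:
        report = ", ".join(
            f"{name}: {p}+/{n}-" for name, p, n in zip(m.task_names, n_pos, n_neg)
        )
        raise ValueError(f"no task passes the {min_pos}+/{min_neg}- filter ({report})")
    return m.select_tasks(keep)


# ---------------------------------------------------------------------------
# Endpoint studies -> binary labels
# ---------------------------------------------------------------------------


def binarize_readouts(
    study: EndpointStudy,
    reducer: str = "any",
) -> SparseLabelMatrix:
    """Binarize continuous readouts against expert thresholds.

    A molecule is positive for an endpoint iff its readout exceeds the
    endpoint threshold at any dose/time combination (``reducer="any"``,
    equivalent to thresholding the max).  Molecules never measured for an
    endpoint stay missing.
    """
    if reducer not in ("any", "max"):
        raise ValueError("reducer must be 'any' or 'max'")
    endpoints = study.endpoints
    for ep in endpoints:
        if ep not in study.thresholds:
            raise ValueError(f"no expert threshold for endpoint {ep!r}")
    mols = study.molecules
    mol_idx = {m: i for i, m in enumerate(mols)}
    values = np.full((len(mols), len(endpoints)), np.nan)
    grouped = study.records.groupby(["molecule", "endpoint"])["value"].max()
    for (mol, ep), vmax in grouped.items():
        j = endpoints.index(ep)
        values[mol_idx[str(mol)], j] = float(vmax > study.thresholds[ep])
    return SparseLabelMatrix(values, endpoints, mols)


def pool_histopathology(
    study: EndpointStudy,
    min_severity: float = 1.0,
    min_compounds: int = 5,
) -> SparseLabelMatrix:
    """Pool ordinal severity grades across dose and time.

    Positive iff the maximum severity over all dose/time conditions reaches
    ``min_severity``.  Endpoint columns are retained only when positive in
    at least ``min_compounds`` unique molecules.
    """
    endpoints = study.endpoints
    mols = study.molecules
    mol_idx = {m: i for i, m in enumerate(mols)}
    values = np.full((len(mols), len(endpoints)), np.nan)
    grouped = study.records.groupby(["molecule", "endpoint"])["value"].max()
    for (mol, ep), vmax in grouped.items():
        j = endpoints.index(ep)
        values[mol_idx[str(mol)], j] = float(vmax >= min_severity)
    matrix = SparseLabelMatrix(values, endpoints, mols)
    n_pos, _ = matrix.counts()
    keep = [j for j in range(matrix.n_tasks) if n_pos[j] >= min_compounds]
    return matrix.select_tasks(keep)


def aggregate_binary(m: SparseLabelMatrix, name: str = "DILI_binary") -> SparseLabelMatrix:
    """Append an any-task-positive aggregate column.

    The aggregate is 1 when any observed task is positive, 0 when every
    observed task is negative, and missing when no task is observed.
    """
    if m.n_tasks < 1:
        raise ValueError("need at least one task to aggregate")
    obs = m.observed
    any_pos = np.nansum(m.values, axis=1) > 0
    any_obs = obs.any(axis=1)
    agg = np.where(any_obs, any_pos.astype(np.float64), np.nan)
    values = np.column_stack([m.values, agg])
    return SparseLabelMatrix(values, list(m.task_names) + [name], m.molecule_ids)
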