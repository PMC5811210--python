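"""Representational similarity analysis: condition-mean patterns, 1 - Pearson
RDMs, binary model RDMs, and their vectorized (RDV) forms.

All cross-modal analyses in this package operate on 32 conditions (4 tasks x
8 object categories by default) in a fixed *task-major* ordering:
``(task 0, cat 0), (task 0, cat 1), ..., (task 3, cat 7)``.  Every artifact
carries its ordering explicitly and operations that combine RDMs verify
ordering equality rather than assuming it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RDM",
    "ModelRDM",
    "task_major_conditions",
    "condition_mean_patterns",
    "compute_rdm",
    "rdm_timeseries",
    "model_rdm",
    "rdv",
    "rdv_to_matrix",
    "group_average_rdm",
]


def task_major_conditions(n_tasks: int = 4, n_categories: int = 8) -> list[tuple[int, int]]:
    """Canonical condition ordering: task-major list of (task, category)."""
    return [(t, c) for t in range(n_tasks) for c in range(n_categories)]


@dataclass
class RDM:
    """A condition dissimilarity matrix (1 - Pearson r).

    ``label`` is a time stamp in ms for MEG series entries or an ROI name
    for fMRI-side matrices.
    """

    values: np.ndarray
    condition_order: list[tuple[int, int]]
    label: object = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM must be square")
        if v.shape[0] != len(self.condition_order):
            raise ValueError("condition_order length does not match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("RDM entries must be finite")
        self.values = v

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]


@dataclass
class ModelRDM(RDM):
    """Binary hypothesis RDM: 0 where two conditions share the factor level,
    1 where they differ."""

    factor: str = ""


def condition_mean_patterns(dataset) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Average trial patterns within each (task, category) cell.

    Parameters
    ----------
    dataset
        A ComponentDataset (or EpochedDataset) with a ``trials`` table
        containing ``task`` and ``category`` columns and ``data`` of shape
        (n_trials, n_features, n_times).

    Returns
    -------
    means : ndarray, shape (n_conditions, n_features, n_times)
    order : list of (task, category) in task-major order
    """
    trials: pd.DataFrame = dataset.trials
    data = dataset.data
    tasks = np.asarray(trials["task"])
    cats = np.asarray(trials["category"])
    order = task_major_conditions(int(tasks.max()) + 1, int(cats.max()) + 1)
    means = np.empty((len(order),) + data.shape[1:], dtype=float)
    for i, (t, c) in enumerate(order):
        sel = (tasks == t) & (cats == c)
        if not sel.any():
            raise ValueError(f"no trials for condition (task={t}, category={c})")
        means[i] = data[sel].mean(axis=0)
    return means, order


def compute_rdm(patterns: np.ndarray, condition_order=None, label=None) -> RDM:
    """1 - Pearson correlation dissimilarity between condition patterns.

    ``patterns`` has shape (n_conditions, n_features).
    """
    p = np.asarray(patterns, dtype=float)
    if p.ndim != 2:
        raise ValueError("patterns must be 2-D (conditions x features)")
    sd = p.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"pattern {bad} has zero variance; correlation undefined")
    r = np.corrcoef(p)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    if condition_order is None:
        condition_order = task_major_conditions(1, p.shape[0])
    return RDM(d, list(condition_order), label=label)


def rdm_timeseries(mean_patterns: np.ndarray, time_ms: np.ndarray,
                   condition_order) -> list[RDM]:
    """Per-timepoint RDMs from (n_conditions, n_features, n_times) means."""
    n_cond, _, n_t = mean_patterns.shape
    centered = mean_patterns - mean_patterns.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-variance pattern in RDM time series")
    z = centered / norms[:, None, :]
    # r[t] = z[:,:,t] @ z[:,:,t].T for all t at once
    r = np.einsum("ift,jft->tij", z, z)
    out = []
    for ti in range(n_t):
        d = 1.0 - r[ti]
        np.fill_diagonal(d, 0.0)
        out.append(RDM(d, list(condition_order), label=float(time_ms[ti])))
    return out


def model_rdm(factor: str, condition_order) -> ModelRDM:
    """Binary model RDM for ``factor`` in {"task", "category"}."""
    idx = {"task": 0, "category": 1}
    if factor not in idx:
        raise ValueError(f"unknown factor {factor!r}; expected 'task' or 'category'")
    levels = np.array([cond[idx[factor]] for cond in condition_order])
    m = (levels[:, None] != levels[None, :]).astype(float)
    return ModelRDM(m, list(condition_order), factor=factor)


def rdv(rdm, atol: float = 1e-10) -> np.ndarray:
    """Lower-triangle vector of an RDM, excluding the diagonal.

    The scan is column-major over the lower triangle (the squareform
    convention), length n(n-1)/2 — 496 entries for 32 conditions.
    """
    m = rdm.values if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def rdv_to_matrix(v: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from an RDV."""
    v = np.asarray(v, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * v.size)) / 2))
    if n * (n - 1) // 2 != v.size:
        raise ValueError("RDV length is not n(n-1)/2 for integer n")
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = v
    return m + m.T


def group_average_rdm(rdms: list[RDM]) -> RDM:
    """Entrywise mean of RDMs sharing one condition ordering."""
    if not rdms:
        raise ValueError("empty RDM list")
    ref = rdms[0].condition_order
    for r in rdms[1:]:
        if r.condition_order != ref:
            raise ValueError("condition ordering mismatch between RDMs")
    return RDM(np.mean([r.values for r in rdms], axis=0), list(ref),
               label=rdms[0].label)
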