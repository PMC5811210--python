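"""Model-based MEG-fMRI fusion via commonality analysis.

For a time-resolved MEG RDV ``X_t`` and an fMRI ROI RDV ``Y_j``, the fusion
time course is the squared Spearman correlation R²(X_t, Y_j) — the variance
in the MEG representational geometry explained by the ROI's geometry.  The
commonality analysis partitions this shared variance between two binary
model RDVs, task (A) and object category (B):

    C(X_t, (Y_j, A)) = R²(X_t, Y_j.B) − R²(X_t, Y_j.A,B)

where ``Y.B`` denotes the squared semi-partial (Spearman) correlation of X
with Y after residualizing Y's ranks on B's ranks.  C_task is the
MEG-fMRI shared variance uniquely attributable to the task model (C_cat
symmetric with roles swapped).  Commonalities can exceed the total R²
slightly or go slightly negative (suppression / numerical effects) and are
deliberately not clipped.

Ranks use average tie-ranking (binary model RDVs are massively tied, so the
tie policy matters and is fixed here); residualization includes an
intercept; vectors are rank-transformed first and residualized second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .rsa import RDM, ModelRDM, rdv

__all__ = [
    "FusionResult", "spearman_r2", "semipartial_spearman_r2", "commonality",
    "run_fusion",
]


@dataclass
class FusionResult:
    """Per-ROI fusion time courses.

    ``r2_total``, ``c_task`` and ``c_category`` map ROI name to arrays of
    length ``len(time_ms)``.  ``target`` records whether models were
    partialled out of the fMRI RDV (default, "fmri") or the MEG RDV.
    """

    time_ms: np.ndarray
    r2_total: dict[str, np.ndarray]
    c_task: dict[str, np.ndarray]
    c_category: dict[str, np.ndarray]
    condition_order: list = field(default_factory=list)
    target: str = "fmri"

    @property
    def rois(self) -> list[str]:
        return list(self.r2_total)


def _check_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if np.ptp(v) == 0:
        raise ValueError(f"{name} is constant; rank correlation undefined")
    return v


def spearman_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Spearman rank correlation, in [0, 1]."""
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    rx, ry = rankdata(x), rankdata(y)
    r = np.corrcoef(rx, ry)[0, 1]
    return float(r * r)


def _residualize(ry: np.ndarray, partial_ranks: list[np.ndarray]) -> np.ndarray:
    design = np.column_stack([np.ones_like(ry)] + partial_ranks)
    coef, *_ = np.linalg.lstsq(design, ry, rcond=None)
    return ry - design @ coef


def semipartial_spearman_r2(x: np.ndarray, y: np.ndarray,
                            partial_set: list[np.ndarray]) -> float:
    """Squared semi-partial Spearman correlation.

    All vectors are rank-transformed; ``y``'s ranks are residualized on the
    ranks of the partial set (with intercept) by least squares; the squared
    Pearson correlation between ``x``'s ranks and the residual is returned.
    A residual with (near-)zero variance means y is fully explained by the
    partial set; the semi-partial R² is then 0, with a warning.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    parts = [rankdata(_check_vector(p, "partial vector")) for p in partial_set]
    for p in parts:
        if p.size != y.size:
            raise ValueError("length mismatch in partial set")
    rx, ry = rankdata(x), rankdata(y)
    if not parts:
        r = np.corrcoef(rx, ry)[0, 1]
        return float(r * r)
    resid = _residualize(ry, parts)
    var = resid.var()
    if var <= 1e-12 * ry.var():
        warnings.warn("y is fully explained by the partial set; "
                      "semi-partial R^2 set to 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(rx, resid)[0, 1]
    return float(r * r)


def commonality(x: np.ndarray, y: np.ndarray, a: np.ndarray,
                b: np.ndarray) -> tuple[float, float, float]:
    """Commonality coefficients for two models.

    Returns (C_a, C_b, R2_total) where
    C_a = sp_R²(x, y | {b}) − sp_R²(x, y | {a, b}) and C_b symmetrically.
    Values are not clipped to [0, R2_total].
    """
    r2_ab = semipartial_spearman_r2(x, y, [a, b])
    c_a = semipartial_spearman_r2(x, y, [b]) - r2_ab
    c_b = semipartial_spearman_r2(x, y, [a]) - r2_ab
    return float(c_a), float(c_b), spearman_r2(x, y)


def _rank_rows(m: np.ndarray) -> np.ndarray:
    return rankdata(m, axis=1, method="average")


def _standardize(v: np.ndarray, axis=-1) -> np.ndarray:
    c = v - v.mean(axis=axis, keepdims=True)
    n = np.linalg.norm(c, axis=axis, keepdims=True)
    # zero-variance vectors correlate with nothing: map them to zero rather
    # than propagating NaN through the vectorized fusion path
    return c / np.where(n == 0, np.inf, n)


def fusion_curves(meg_rdvs: np.ndarray, fmri_rdv: np.ndarray,
                  model_a_rdv: np.ndarray, model_b_rdv: np.ndarray,
                  target: str = "fmri") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized commonality over a (n_times, n_pairs) stack of MEG RDVs.

    With target="fmri" (default, matching the commonality formula) the
    model ranks are partialled out of the fMRI RDV; with target="meg" they
    are partialled out of the MEG RDVs instead (the alternative target
    variable; the two need not agree exactly).
    Returns (r2_total, c_a, c_b) arrays of length n_times.
    """
    rx = _rank_rows(np.atleast_2d(meg_rdvs))
    ry = rankdata(fmri_rdv)
    ra, rb = rankdata(model_a_rdv), rankdata(model_b_rdv)

    if target == "fmri":
        zx = _standardize(rx)
        zv = np.stack([_standardize(v) for v in
                       (ry, _residualize(ry, [rb]), _residualize(ry, [ra]),
                        _residualize(ry, [ra, rb]))], axis=0)  # (4, n_pairs)
        c = (zx @ zv.T) ** 2  # squared Pearson of rank vectors, (n_times, 4)
        r2_total, r2_b, r2_a, r2_ab = c[:, 0], c[:, 1], c[:, 2], c[:, 3]
    elif target == "meg":
        zy = _standardize(ry)
        x_b = rx - _project(rx, [rb])
        x_a = rx - _project(rx, [ra])
        x_ab = rx - _project(rx, [ra, rb])
        r2_total = (_standardize(rx) @ zy) ** 2
        r2_b = (_standardize(x_b) @ zy) ** 2
        r2_a = (_standardize(x_a) @ zy) ** 2
        r2_ab = (_standardize(x_ab) @ zy) ** 2
    else:
        raise ValueError("target must be 'fmri' or 'meg'")
    return r2_total, r2_b - r2_ab, r2_a - r2_ab


def _project(rows: np.ndarray, partial_ranks: list[np.ndarray]) -> np.ndarray:
    design = np.column_stack([np.ones(rows.shape[1])] + partial_ranks)
    coef, *_ = np.linalg.lstsq(design, rows.T, rcond=None)
    return (design @ coef).T


def run_fusion(meg_rdms: list[RDM], fmri_rdms: dict[str, RDM],
               task_model: ModelRDM, category_model: ModelRDM,
               target: str = "fmri") -> FusionResult:
    """Commonality time courses for every ROI.

    All RDMs must share one condition ordering; MEG RDMs are expected to be
    group averages (as are the ROI RDMs).
    """
    order = meg_rdms[0].condition_order
    for r in meg_rdms[1:]:
        if r.condition_order != order:
            raise ValueError("condition ordering mismatch within MEG series")
    for name, r in fmri_rdms.items():
        if r.condition_order != order:
            raise ValueError(f"condition ordering mismatch for ROI {name!r}")
    for m in (task_model, category_model):
        if m.condition_order != order:
            raise ValueError("condition ordering mismatch for model RDM")

    time_ms = np.array([float(r.label) for r in meg_rdms])
    meg_rdvs = np.stack([rdv(r) for r in meg_rdms])
    a = rdv(task_model)
    b = rdv(category_model)
    r2_total, c_task, c_cat = {}, {}, {}
    for name, roi in fmri_rdms.items():
        r2, ca, cb = fusion_curves(meg_rdvs, rdv(roi), a, b, target=target)
        r2_total[name], c_task[name], c_cat[name] = r2, ca, cb
    return FusionResult(time_ms, r2_total, c_task, c_cat,
                        condition_order=list(order), target=target)
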