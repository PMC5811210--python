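"""Nonparametric cluster-based inference and bootstrap latency intervals.

Sign-permutation tests: under the null each subject's (chance-subtracted)
effect is symmetric around zero, so flipping subject signs generates the
null distribution of the group t statistic.  The cluster-inducing threshold
is the 95th percentile of the permutation t distribution at each point;
clusters are maximal runs (1D) or 4-connected components (2D) of
supra-threshold points; family-wise error is controlled by comparing the
observed cluster sizes (extent in samples) with the 95th percentile of the
permutation distribution of the maximum cluster size.  All tests are
one-sided (above chance/null).  The identity sign assignment is always a
member of the permutation set, so p-values are never 0.

For fusion time courses, where there is one group-average MEG RDM series
rather than per-subject curves, the null is built by jointly permuting rows
and columns (condition relabelling) of the group-average MEG RDMs and
re-running the fusion; the maximum-cluster-size null is pooled across ROIs
to correct for multiple comparisons.

Bootstrap peak-latency confidence intervals resample subjects with
replacement, recompute the group curve (for fusion: re-average the MEG RDMs
and rerun fusion), and take the 2.5/97.5 percentiles of the latency
statistic.  CI endpoints live on the sampled time grid, so they are
conservative by up to two sample periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import fusion as _fusion
from .rsa import RDM, ModelRDM, rdv

__all__ = [
    "Cluster", "ClusterResult", "PeakCI",
    "sign_permutation_cluster_1d", "cluster_2d",
    "rdm_randomization_cluster", "bootstrap_peak_ci",
]


# finite stand-in for the t statistic of a zero-variance sample; keeps
# quantiles well defined while dominating any real t value
_T_CAP = 1e12


@dataclass
class Cluster:
    """One candidate cluster: its index set, extent and p-value."""

    indices: tuple
    size: int
    p_value: float
    significant: bool


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: np.ndarray          # cluster-inducing threshold per point
    observed_stat: np.ndarray      # group t (or fusion statistic) per point
    critical_size: float           # 95th pct of the max-cluster-size null
                                   # (reported; significance uses the exact
                                   # permutation p-value <= alpha)
    n_permutations: int
    seed: int | None = None
    exhaustive: bool = False

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


@dataclass
class PeakCI:
    """Bootstrap latency estimate with its percentile confidence interval."""

    estimate_ms: float
    ci_low_ms: float
    ci_high_ms: float
    n_boot: int
    window_ms: tuple[float, float]
    mode: str
    flat_curve: bool = False


def _t_stat(x: np.ndarray, axis: int = 0) -> np.ndarray:
    n = x.shape[axis]
    m = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd == 0, np.sign(m) * _T_CAP, t)


def _perm_t(signs: np.ndarray, x: np.ndarray) -> np.ndarray:
    """t statistics for every sign assignment.

    ``signs``: (P, n) in {-1, +1}; ``x``: (n, T) chance-subtracted data.
    Sign flips change the mean but not sum(x^2), so the permutation t
    follows from the flipped means and the fixed per-point sum of squares.
    """
    n, T = x.shape
    m = signs @ x / n                             # (P, T)
    ss = np.sum(x * x, axis=0)                    # (T,)
    var = (ss[None, :] - n * m * m) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    return np.where(var == 0, np.sign(m) * _T_CAP, t)


def _all_signs(n: int) -> np.ndarray:
    idx = np.arange(2 ** n, dtype=np.uint64)
    bits = (idx[:, None] >> np.arange(n, dtype=np.uint64)[None, :]) & 1
    return (bits.astype(np.float32) * 2 - 1)


def _sample_signs(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """``n_perm`` distinct sign assignments, identity included."""
    total = 2 ** n
    if n_perm > total:
        raise ValueError(f"n_perm={n_perm} exceeds 2^{n}={total} assignments")
    if n_perm == total:
        return _all_signs(n)
    if total <= 2 ** 24:
        chosen = rng.choice(total, size=n_perm, replace=False)
    else:
        seen: set[int] = set()
        while len(seen) < n_perm:
            seen.update(rng.integers(0, total, size=n_perm - len(seen)).tolist())
        chosen = np.fromiter(seen, dtype=np.uint64, count=n_perm)
    identity = total - 1  # all bits set -> all +1
    if identity not in chosen:
        chosen[0] = identity
    bits = (chosen.astype(np.uint64)[:, None]
            >> np.arange(n, dtype=np.uint64)[None, :]) & 1
    return bits.astype(np.float32) * 2 - 1


def _max_run_lengths(b: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a 2-D boolean array (vectorized)."""
    z = np.cumsum(b, axis=1)
    resets = np.maximum.accumulate(np.where(b, 0, z), axis=1)
    return np.max(np.where(b, z - resets, 0), axis=1)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs in a 1-D mask."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts, stops))


def sign_permutation_cluster_1d(subject_curves: np.ndarray, chance: float = 0.0,
                                alpha: float = 0.05,
                                max_exhaustive: int = 2 ** 17,
                                n_perm: int = 10000, seed: int | None = None,
                                time_mask: np.ndarray | None = None) -> ClusterResult:
    """One-sided maximum-cluster-size sign-permutation test on time courses.

    ``subject_curves``: (n_subjects, n_times).  All 2^n sign assignments
    are enumerated when 2^n <= max_exhaustive (131,072 at n = 17);
    otherwise ``n_perm`` distinct assignments are sampled.  ``time_mask``
    optionally restricts inference to a time window.
    """
    x = np.asarray(subject_curves, dtype=float) - chance
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 subjects of equal-length curves")
    n, T = x.shape
    exhaustive = 2 ** n <= max_exhaustive
    rng = np.random.default_rng(seed)
    signs = _all_signs(n) if exhaustive else _sample_signs(n, n_perm, rng)
    t_perm = _perm_t(signs, x)
    threshold = np.quantile(t_perm, 1 - alpha, axis=0)
    t_obs = _t_stat(x)

    mask = np.ones(T, dtype=bool) if time_mask is None else np.asarray(time_mask, bool)
    supra_obs = (t_obs > threshold) & mask
    supra_perm = (t_perm > threshold[None, :]) & mask[None, :]
    null_max = _max_run_lengths(supra_perm)
    critical = float(np.quantile(null_max, 1 - alpha, method="higher"))

    clusters = []
    for start, stop in _runs(supra_obs):
        size = stop - start
        p = float(np.mean(null_max >= size))
        clusters.append(Cluster(tuple(range(start, stop)), size, p,
                                p <= alpha))
    return ClusterResult(clusters, threshold, t_obs, critical,
                         signs.shape[0], seed=seed, exhaustive=exhaustive)


def cluster_2d(subject_matrices: np.ndarray, chance: float = 0.0,
               n_perm: int = 10000, alpha: float = 0.05,
               seed: int | None = None) -> ClusterResult:
    """2-D extension of the sign-permutation cluster test (4-connectivity).

    ``subject_matrices``: (n_subjects, T1, T2).  ``n_perm`` distinct sign
    assignments are drawn without replacement from the 2^n available
    (error if n_perm exceeds that).
    """
    x = np.asarray(subject_matrices, dtype=float) - chance
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need >= 2 subjects of train x test matrices")
    n, t1, t2 = x.shape
    rng = np.random.default_rng(seed)
    signs = _sample_signs(n, n_perm, rng)
    flat = x.reshape(n, -1)
    t_perm = _perm_t(signs, flat)
    threshold = np.quantile(t_perm, 1 - alpha, axis=0)
    t_obs = _t_stat(flat)

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    supra_perm = (t_perm > threshold[None, :]).reshape(-1, t1, t2)
    null_max = np.empty(signs.shape[0])
    for p in range(signs.shape[0]):
        lab, nlab = ndimage.label(supra_perm[p], structure=structure)
        null_max[p] = np.bincount(lab.ravel())[1:].max() if nlab else 0
    critical = float(np.quantile(null_max, 1 - alpha, method="higher"))

    supra_obs = (t_obs > threshold).reshape(t1, t2)
    lab, nlab = ndimage.label(supra_obs, structure=structure)
    clusters = []
    for k in range(1, nlab + 1):
        idx = np.nonzero(lab == k)
        size = idx[0].size
        p_val = float(np.mean(null_max >= size))
        clusters.append(Cluster(tuple(zip(idx[0].tolist(), idx[1].tolist())),
                                size, p_val, p_val <= alpha))
    return ClusterResult(clusters, threshold.reshape(t1, t2),
                         t_obs.reshape(t1, t2), critical, signs.shape[0],
                         seed=seed, exhaustive=False)


def _permuted_rdvs(rdm_stack: np.ndarray, perm: np.ndarray,
                   iu: tuple) -> np.ndarray:
    permuted = rdm_stack[:, perm][:, :, perm]
    return permuted[:, iu[0], iu[1]]


def rdm_randomization_cluster(group_meg_rdms: list[RDM],
                              fmri_rdms: dict[str, RDM],
                              task_model: ModelRDM, category_model: ModelRDM,
                              statistic: str = "c_task", n_perm: int = 5000,
                              alpha: float = 0.05, seed: int | None = None,
                              time_mask: np.ndarray | None = None
                              ) -> dict[str, ClusterResult]:
    """Condition-relabelling cluster test for fusion time courses.

    Each permutation applies one random permutation jointly to the rows and
    columns of every time point's group-average MEG RDM (preserving
    symmetry and the zero diagonal), reruns the fusion, and records the
    null statistic.  Per-ROI, per-time thresholds are the (1-alpha)
    quantile of the null; the max-cluster-size null is pooled across ROIs
    (multiple-comparison correction).  ``statistic`` is one of
    {"r2", "c_task", "c_category"}.
    """
    stat_idx = {"r2": 0, "c_task": 1, "c_category": 2}[statistic]
    order = group_meg_rdms[0].condition_order
    n_cond = len(order)
    iu = np.triu_indices(n_cond, k=1)
    rdm_stack = np.stack([r.values for r in group_meg_rdms])
    time_len = rdm_stack.shape[0]
    a = rdv(task_model)
    b = rdv(category_model)
    roi_rdvs = {name: rdv(r) for name, r in fmri_rdms.items()}

    observed = {}
    for name, y in roi_rdvs.items():
        obs = _fusion.fusion_curves(rdm_stack[:, iu[0], iu[1]], y, a, b)
        observed[name] = obs[stat_idx]

    rng = np.random.default_rng(seed)
    rois = list(roi_rdvs)
    null = np.empty((n_perm, len(rois), time_len))
    for p in range(n_perm):
        perm = np.arange(n_cond) if p == 0 else rng.permutation(n_cond)
        meg_rdvs = _permuted_rdvs(rdm_stack, perm, iu)
        for ri, name in enumerate(rois):
            null[p, ri] = _fusion.fusion_curves(meg_rdvs, roi_rdvs[name],
                                                a, b)[stat_idx]

    mask = np.ones(time_len, bool) if time_mask is None else np.asarray(time_mask, bool)
    thresholds = np.quantile(null, 1 - alpha, axis=0)   # (rois, T)
    # pooled max cluster size: max over ROIs within each permutation
    supra = (null > thresholds[None, :, :]) & mask[None, None, :]
    per_roi_max = np.stack([_max_run_lengths(supra[:, ri, :])
                            for ri in range(len(rois))], axis=1)
    null_max = per_roi_max.max(axis=1)
    critical = float(np.quantile(null_max, 1 - alpha, method="higher"))

    results = {}
    for ri, name in enumerate(rois):
        supra_obs = (observed[name] > thresholds[ri]) & mask
        clusters = []
        for start, stop in _runs(supra_obs):
            size = stop - start
            p_val = float(np.mean(null_max >= size))
            clusters.append(Cluster(tuple(range(start, stop)), size, p_val,
                                    p_val <= alpha))
        results[name] = ClusterResult(clusters, thresholds[ri], observed[name],
                                      critical, n_perm, seed=seed)
    return results


def bootstrap_peak_ci(subject_data, time_ms: np.ndarray,
                      window_ms: tuple[float, float], n_boot: int = 10000,
                      mode: str = "peak", seed: int | None = None,
                      curve_fn=None, subject_data_b=None,
                      onset_criterion: float | None = None) -> PeakCI:
    """Bootstrap confidence interval for a latency statistic.

    ``subject_data`` is (n_subjects, n_times) curves, or any per-subject
    sequence if ``curve_fn`` is given (``curve_fn(mean_over_subjects) ->
    curve``; for fusion, pass per-subject MEG RDM stacks and a function
    that reruns fusion on their average).  Modes:

    - "peak": latency of the maximum inside the window;
    - "peak_difference": peak latency difference between ``subject_data``
      and ``subject_data_b`` (paired resampling);
    - "onset": first time in the window where the curve reaches
      ``onset_criterion`` (a criterion-crossing stand-in for onset).

    A flat curve in the window yields the earliest maximum and sets
    ``flat_curve``.
    """
    data = np.asarray(subject_data, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    t = np.asarray(time_ms, dtype=float)
    win = (t >= window_ms[0]) & (t <= window_ms[1])
    if not win.any():
        raise ValueError("window outside the time axis")
    tw = t[win]
    if curve_fn is None:
        curve_fn = lambda avg: avg

    flat_seen = False

    def latency(avg, avg_b=None):
        nonlocal flat_seen
        curve = np.asarray(curve_fn(avg))[win]
        if np.ptp(curve) == 0:
            flat_seen = True
        if mode == "peak":
            return tw[int(np.argmax(curve))]
        if mode == "peak_difference":
            curve_b = np.asarray(curve_fn(avg_b))[win]
            if np.ptp(curve_b) == 0:
                flat_seen = True
            return tw[int(np.argmax(curve))] - tw[int(np.argmax(curve_b))]
        if mode == "onset":
            if onset_criterion is None:
                raise ValueError("onset mode requires onset_criterion")
            above = curve >= onset_criterion
            if not above.any():
                flat_seen = True
                return tw[-1]
            return tw[int(np.argmax(above))]
        raise ValueError(f"unknown mode {mode!r}")

    data_b = None
    if mode == "peak_difference":
        if subject_data_b is None:
            raise ValueError("peak_difference mode needs subject_data_b")
        data_b = np.asarray(subject_data_b, dtype=float)

    point = latency(data.mean(axis=0),
                    None if data_b is None else data_b.mean(axis=0))
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        draws[i] = latency(data[idx].mean(axis=0),
                           None if data_b is None else data_b[idx].mean(axis=0))
    # closest-observation quantiles keep CI endpoints on the time grid
    lo, hi = np.quantile(draws, [0.025, 0.975], method="closest_observation")
    if flat_seen:
        warnings.warn("flat curve encountered in the latency window; "
                      "earliest maximum used", stacklevel=2)
    return PeakCI(float(point), float(min(lo, point)), float(max(hi, point)),
                  n_boot, tuple(window_ms), mode, flat_curve=flat_seen)
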