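"""Batched linear SVM training.

Time-resolved decoding trains one tiny linear SVM per time point, per class
pair, per iteration — millions of fits per subject.  This module solves
many such problems at once: the dual of the L1-loss (hinge) soft-margin SVM
with the bias absorbed as a constant appended feature, optimized by dual
coordinate descent over precomputed Gram matrices, JIT-compiled with numba.
The formulation is identical to liblinear's dual L1-loss SVC with bias
augmentation (sklearn ``LinearSVC(loss="hinge")``), which serves as the
cross-check oracle in the test suite.

All problems in a batch share the same label vector (the batch axis is
time; the supertrial class structure is fixed within an iteration).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["BatchSVMResult", "fit_linear_svm_batch", "solve_dual_from_gram"]


@njit(cache=True)
def _cd_solve_gram(K, y, C, tol, max_passes):  # pragma: no cover - jitted
    B, n, _ = K.shape
    alpha = np.zeros((B, n))
    for b in range(B):
        a = alpha[b]
        grad = np.full(n, -1.0)
        for _ in range(max_passes):
            max_viol = 0.0
            for i in range(n):
                g = grad[i]
                ai = a[i]
                if ai <= 0.0 and g > 0.0:
                    continue
                if ai >= C and g < 0.0:
                    continue
                if g > max_viol:
                    max_viol = g
                elif -g > max_viol:
                    max_viol = -g
                qii = K[b, i, i]
                if qii <= 0.0:
                    continue
                na = ai - g / qii
                if na < 0.0:
                    na = 0.0
                elif na > C:
                    na = C
                delta = na - ai
                if delta != 0.0:
                    a[i] = na
                    yidelta = delta * y[i]
                    for j in range(n):
                        grad[j] += yidelta * y[j] * K[b, i, j]
            if max_viol <= tol:
                break
    return alpha


class BatchSVMResult:
    """Weights (batch, n_features), biases (batch,) and dual coefficients."""

    __slots__ = ("w", "b", "alpha")

    def __init__(self, w: np.ndarray, b: np.ndarray, alpha: np.ndarray):
        self.w = w
        self.b = b
        self.alpha = alpha

    def decision(self, x: np.ndarray) -> np.ndarray:
        """Decision values for test patterns: (batch, m, n_features) scored
        problem-by-problem, or (m, n_features) broadcast to every problem."""
        if x.ndim == 2:
            return self.w @ x.T + self.b[:, None]
        return np.einsum("bmf,bf->bm", x, self.w) + self.b[:, None]


def solve_dual_from_gram(K: np.ndarray, y: np.ndarray, C: float = 1.0,
                         tol: float = 1e-3, max_passes: int = 200) -> np.ndarray:
    """Dual coefficients alpha (batch, n) from bias-augmented Gram matrices
    ``K`` of shape (batch, n, n) with K_ij = x_i.x_j + 1.

    Decision values for a test kernel row k (with the same +1 augmentation)
    are ``sum_i alpha_i y_i k_i``.
    """
    K = np.ascontiguousarray(K, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if K.ndim != 3 or K.shape[1] != K.shape[2]:
        raise ValueError("K must be (batch, n, n)")
    if y.size != K.shape[1]:
        raise ValueError("label length mismatch")
    if not np.all(np.abs(y) == 1):
        raise ValueError("labels must be +/-1")
    return _cd_solve_gram(K, y, float(C), float(tol), int(max_passes))


def fit_linear_svm_batch(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                         tol: float = 1e-4, max_passes: int = 1000) -> BatchSVMResult:
    """Train one linear SVM per batch element.

    Parameters
    ----------
    X : ndarray, shape (batch, n_samples, n_features)
        Training patterns; one independent problem per batch element.
    y : ndarray, shape (n_samples,)
        Labels in {-1, +1}, shared across the batch.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("X must be (batch, samples, features)")
    K = np.einsum("bif,bjf->bij", X, X) + 1.0
    alpha = solve_dual_from_gram(K, y, C=C, tol=tol, max_passes=max_passes)
    ay = alpha * np.asarray(y, dtype=float)[None, :]
    w = np.einsum("bn,bnf->bf", ay, X)
    b = ay.sum(axis=1)  # weight on the constant augmented feature
    return BatchSVMResult(w, b, alpha)
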