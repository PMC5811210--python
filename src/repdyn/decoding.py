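"""Time-resolved pairwise decoding with supertrial averaging.

One decoding iteration: trials of each class are randomly partitioned into
disjoint groups of ``supertrial_size`` and averaged into supertrials; one
supertrial per class is held out as test data; for every unordered class
pair and every time point an independent linear SVM (C = 1 by default) is
trained on the remaining supertrials; the held-out pair is scored by
*ordering accuracy* — 100% if the positive-class sample's decision value
exceeds the negative-class sample's, 0% if reversed, 50% on a tie (for two
samples and two classes this equals the two-sample area under the ROC curve
and does not depend on the classifier's bias term).  Pairwise accuracies
are averaged (28 pairs for 8 categories, 6 for 4 tasks; chance 50%), and
the final curve is the mean over ``n_iterations`` such iterations.

Temporal generalization evaluates each training-time classifier at every
testing time with the same held-out supertrials, yielding a time-time
accuracy matrix.  Cross task-type decoding trains object classifiers within
one task type (perceptual = color/tilt, conceptual = content/size) and
tests on held-out supertrials from the same vs the other type.

Classification at time t uses only data at time t: classifiers are trained
and tested on single-time-point component patterns (the SVMs for all time
points of a pair are solved as one batch, but the problems are independent).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._svm import fit_linear_svm_batch, solve_dual_from_gram
from .preprocess import ComponentDataset
from .synth import CONCEPTUAL_TASKS, PERCEPTUAL_TASKS

__all__ = [
    "DecodingConfig", "SupertrialSet", "AccuracyTimecourse",
    "TemporalGeneralizationMatrix", "make_supertrials", "ordering_accuracy",
    "decode_timecourse", "cross_tasktype_object_decode",
    "temporal_generalization",
]

CHANCE_PERCENT = 50.0


@dataclass(frozen=True)
class DecodingConfig:
    """Decoding parameters: which factor to decode, supertrial group size,
    number of averaging iterations, SVM penalty C, and the RNG seed."""

    label_factor: str = "category"
    supertrial_size: int = 10
    n_iterations: int = 500
    C: float = 1.0
    seed: int = 0
    svm_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.supertrial_size < 1:
            raise ValueError("supertrial_size must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass
class SupertrialSet:
    """Per-class supertrials (averages of disjoint trial groups).

    ``supertrials[c]`` has shape (n_groups, n_features, n_times);
    ``mapping[c]`` lists the source-trial indices of each group.  Leftover
    trials (class count not divisible by the group size) are unused for
    this iteration.
    """

    supertrials: dict
    mapping: dict
    group_size: int

    @property
    def classes(self) -> list:
        return list(self.supertrials)


@dataclass
class AccuracyTimecourse:
    """Decoding accuracy (%) per time point for one subject."""

    accuracy: np.ndarray
    time_ms: np.ndarray
    factor: str
    chance: float = CHANCE_PERCENT
    subject_id: str = ""
    config: DecodingConfig | None = None

    def __post_init__(self) -> None:
        if self.accuracy.shape != self.time_ms.shape:
            raise ValueError("accuracy and time axis lengths differ")
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 100):
            raise ValueError("accuracies must be in [0, 100]")


@dataclass
class TemporalGeneralizationMatrix:
    """Accuracy (%) indexed by (training time, testing time)."""

    accuracy: np.ndarray
    time_ms: np.ndarray
    factor: str
    chance: float = CHANCE_PERCENT
    subject_id: str = ""
    config: DecodingConfig | None = None

    def __post_init__(self) -> None:
        n = self.time_ms.size
        if self.accuracy.shape != (n, n):
            raise ValueError("generalization matrix must be square in time")


def _experimental(dataset: ComponentDataset, include_catch: bool):
    """Analysis subset of the trials (catch excluded by default), as a
    float32 view/copy to keep the decoding working set small."""
    trials = dataset.trials
    if include_catch or "is_catch" not in trials:
        data, tab = dataset.data, trials
    else:
        mask = ~np.asarray(trials["is_catch"], dtype=bool)
        if mask.all():
            data, tab = dataset.data, trials
        else:
            data, tab = dataset.data[mask], trials[mask].reset_index(drop=True)
    return np.ascontiguousarray(data, dtype=np.float32), tab


def make_supertrials(dataset: ComponentDataset, label_factor: str,
                     group_size: int, rng_seed, include_catch: bool = False,
                     data=None, labels=None) -> SupertrialSet:
    """Randomly partition each class's trials into disjoint groups of
    ``group_size`` and average within groups (sampling without replacement;
    floor(n_class / group_size) supertrials per class, remainders unused)."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    if data is None:
        data, trials = _experimental(dataset, include_catch)
        labels = np.asarray(trials[label_factor])
    supertrials, mapping = {}, {}
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < group_size:
            raise ValueError(
                f"class {cls!r} has {idx.size} trials; need >= {group_size}")
        k = idx.size // group_size
        perm = rng.permutation(idx)[:k * group_size].reshape(k, group_size)
        supertrials[cls] = data[perm.reshape(-1)].reshape(
            (k, group_size) + data.shape[1:]).mean(axis=1, dtype=data.dtype)
        mapping[cls] = perm.tolist()
    return SupertrialSet(supertrials, mapping, group_size)


def ordering_accuracy(decision_values, true_classes, positive_class=None) -> float:
    """Score a held-out pair by the predicted ordering of decision values.

    ``decision_values`` holds one value per test sample, aligned with
    ``true_classes`` (exactly one sample of each of two classes).  The
    positive class defaults to the lexicographically smaller label.  Returns
    100 if the positive-class sample's value is larger, 0 if smaller, 50 on
    a tie.  The bias term cancels, so the score is bias-independent.
    """
    dv = tuple(decision_values)
    cls = tuple(true_classes)
    if len(dv) != 2 or len(cls) != 2 or cls[0] == cls[1]:
        raise ValueError("need exactly one test sample per class, two classes")
    if positive_class is None:
        positive_class = min(cls)
    pos = cls.index(positive_class)
    diff = dv[pos] - dv[1 - pos]
    return 100.0 if diff > 0 else (0.0 if diff < 0 else 50.0)


def _pair_accuracy(dv: np.ndarray) -> np.ndarray:
    """Vectorized ordering accuracy: dv (..., 2) with the positive-class
    sample first."""
    diff = dv[..., 0] - dv[..., 1]
    return np.where(diff > 0, 100.0, np.where(diff < 0, 0.0, 50.0))


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    # independent, parallelizable per-iteration streams
    return np.random.default_rng([np.uint32(seed), np.uint32(iteration)])


def _pair_kernel(Sa: np.ndarray, Sb: np.ndarray, extras=()) -> np.ndarray:
    """Bias-augmented Gram over the pair's supertrials (plus any extra test
    patterns), per time point: (n_times, m, m)."""
    S = np.concatenate([Sa, Sb, *extras], axis=0)
    return np.einsum("idt,jdt->tij", S, S, optimize=True) + np.float32(1.0)


def _check_provenance(dataset: ComponentDataset, factor: str) -> None:
    prov_factor = dataset.provenance.get("baseline_factor")
    if prov_factor is not None and prov_factor != factor:
        raise ValueError(
            f"dataset was baseline-normalized for {prov_factor!r} decoding "
            f"but {factor!r} decoding was requested")


def decode_timecourse(dataset: ComponentDataset,
                      config: DecodingConfig) -> AccuracyTimecourse:
    """Mean pairwise ordering accuracy per time point (see module docstring)."""
    _check_provenance(dataset, config.label_factor)
    data, trials = _experimental(dataset, include_catch=False)
    labels = np.asarray(trials[config.label_factor])
    classes = np.unique(labels)
    pairs = list(combinations(range(len(classes)), 2))
    n_t = dataset.time_ms.size
    acc = np.zeros(n_t)
    for it in range(config.n_iterations):
        rng = _iteration_rng(config.seed, it)
        sup = make_supertrials(dataset, config.label_factor,
                               config.supertrial_size, rng,
                               data=data, labels=labels)
        counts = {c: len(sup.supertrials[c]) for c in classes}
        ktr_parts, kte_parts, y = [], [], None
        for ia, ib in pairs:
            Sa, Sb = sup.supertrials[classes[ia]], sup.supertrials[classes[ib]]
            ka, kb = counts[classes[ia]], counts[classes[ib]]
            K = _pair_kernel(Sa, Sb)
            tr = np.r_[1:ka, ka + 1:ka + kb]
            te = np.array([0, ka])
            ktr_parts.append(K[:, tr[:, None], tr[None, :]])
            kte_parts.append(K[:, te[:, None], tr[None, :]])
            y = np.concatenate([np.ones(ka - 1), -np.ones(kb - 1)])
        alpha = solve_dual_from_gram(np.concatenate(ktr_parts), y,
                                     C=config.C, tol=config.svm_tol)
        ay = alpha * y
        dv = np.einsum("bmn,bn->bm", np.concatenate(kte_parts).astype(float), ay)
        acc += _pair_accuracy(dv).reshape(len(pairs), n_t).mean(axis=0)
    acc /= config.n_iterations
    return AccuracyTimecourse(acc, dataset.time_ms.copy(), config.label_factor,
                              subject_id=dataset.subject_id, config=config)


def cross_tasktype_object_decode(dataset: ComponentDataset,
                                 config: DecodingConfig
                                 ) -> tuple[AccuracyTimecourse, AccuracyTimecourse]:
    """Object-category decoding within vs between task types.

    Classifiers are trained on supertrials from one task type (perceptual or
    conceptual) and tested on held-out supertrials from the same type
    (within) or from the other type (between); results are averaged over
    both directions, all category pairs and iterations.
    """
    _check_provenance(dataset, "category")
    data, trials = _experimental(dataset, include_catch=False)
    tasks = np.asarray(trials["task"])
    cats = np.asarray(trials["category"])
    type_masks = [np.isin(tasks, PERCEPTUAL_TASKS),
                  np.isin(tasks, CONCEPTUAL_TASKS)]
    classes = np.unique(cats)
    pairs = list(combinations(range(len(classes)), 2))
    n_t = dataset.time_ms.size
    within = np.zeros(n_t)
    between = np.zeros(n_t)
    for it in range(config.n_iterations):
        rng = _iteration_rng(config.seed, it)
        sups = [make_supertrials(dataset, "category", config.supertrial_size,
                                 rng, data=data[m], labels=cats[m])
                for m in type_masks]
        for train_type in (0, 1):
            s_tr = sups[train_type].supertrials
            s_te = sups[1 - train_type].supertrials
            ktr_parts, kw_parts, kb_parts, y = [], [], [], None
            for ia, ib in pairs:
                a, b = classes[ia], classes[ib]
                ka, kb = len(s_tr[a]), len(s_tr[b])
                K = _pair_kernel(s_tr[a], s_tr[b],
                                 extras=(s_te[a][:1], s_te[b][:1]))
                tr = np.r_[1:ka, ka + 1:ka + kb]
                ktr_parts.append(K[:, tr[:, None], tr[None, :]])
                te_w = np.array([0, ka])
                te_b = np.array([ka + kb, ka + kb + 1])
                kw_parts.append(K[:, te_w[:, None], tr[None, :]])
                kb_parts.append(K[:, te_b[:, None], tr[None, :]])
                y = np.concatenate([np.ones(ka - 1), -np.ones(kb - 1)])
            alpha = solve_dual_from_gram(np.concatenate(ktr_parts), y,
                                         C=config.C, tol=config.svm_tol)
            ay = alpha * y
            dv_w = np.einsum("bmn,bn->bm",
                             np.concatenate(kw_parts).astype(float), ay)
            dv_b = np.einsum("bmn,bn->bm",
                             np.concatenate(kb_parts).astype(float), ay)
            within += _pair_accuracy(dv_w).reshape(len(pairs), n_t).mean(axis=0)
            between += _pair_accuracy(dv_b).reshape(len(pairs), n_t).mean(axis=0)
    norm = config.n_iterations * 2
    mk = lambda a: AccuracyTimecourse(a / norm, dataset.time_ms.copy(),
                                      "category", subject_id=dataset.subject_id,
                                      config=config)
    return mk(within), mk(between)


def temporal_generalization(dataset: ComponentDataset, config: DecodingConfig,
                            time_step: int = 1) -> TemporalGeneralizationMatrix:
    """Train at each time point, test the same classifiers at every time
    point, with the same held-out supertrials.

    ``time_step`` decimates the time grid (both axes) to keep the matrix
    tractable; 1 uses the full grid.
    """
    _check_provenance(dataset, config.label_factor)
    data, trials = _experimental(dataset, include_catch=False)
    data = np.ascontiguousarray(data[:, :, ::time_step])
    time_ms = dataset.time_ms[::time_step].copy()
    labels = np.asarray(trials[config.label_factor])
    classes = np.unique(labels)
    pairs = list(combinations(range(len(classes)), 2))
    n_t = time_ms.size
    acc = np.zeros((n_t, n_t))
    for it in range(config.n_iterations):
        rng = _iteration_rng(config.seed, it)
        sup = make_supertrials(dataset, config.label_factor,
                               config.supertrial_size, rng,
                               data=data, labels=labels)
        it_acc = np.zeros((n_t, n_t))
        for ia, ib in pairs:
            Sa, Sb = sup.supertrials[classes[ia]], sup.supertrials[classes[ib]]
            train = np.moveaxis(np.concatenate([Sa[1:], Sb[1:]]), -1, 0)
            y = np.concatenate([np.ones(len(Sa) - 1), -np.ones(len(Sb) - 1)])
            res = fit_linear_svm_batch(train, y, C=config.C,
                                       tol=config.svm_tol)
            test = np.stack([Sa[0], Sb[0]], axis=0)  # (2, d, T)
            # dv[train_time, test_time, sample]
            # dv[train_time, test_time, sample]
            dv = np.einsum("td,eds->tse", res.w, test.astype(float)) \
                + res.b[:, None, None]
            it_acc += _pair_accuracy(dv)
        acc += it_acc / len(pairs)
    acc /= config.n_iterations
    return TemporalGeneralizationMatrix(acc, time_ms, config.label_factor,
                                        subject_id=dataset.subject_id,
                                        config=config)
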