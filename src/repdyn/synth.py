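"""Synthetic data generation with known ground truth.

Emulates a 4-task x 8-category x 5-exemplar x 2-color x 2-tilt factorial
design in which every unique stimulus appears once per task (640 experimental
trials in 20 runs of 32, plus 4 catch trials per run), epochs running from
-100 ms before the task cue to 5000 ms (cue at 0 ms, object stimulus at
2000 ms, response screen at 3500 ms), latent condition-specific spatial
patterns with configurable onset latencies and amplitude envelopes, additive
white Gaussian sensor noise, and fMRI-like ROI condition patterns mixing
task-model and object-model structure with noise.

Tasks 0-1 ("color", "tilt") are perceptual; tasks 2-3 ("content", "size")
are conceptual.  A task-type gain can scale object patterns on conceptual
trials from a given latency, emulating top-down modulation of object
representations by task set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .rsa import task_major_conditions

__all__ = [
    "EPOCH_START_MS", "EPOCH_END_MS", "CUE_ONSET_MS", "STIMULUS_ONSET_MS",
    "RESPONSE_SCREEN_MS", "TASK_NAMES", "PERCEPTUAL_TASKS", "CONCEPTUAL_TASKS",
    "DesignSpec", "DesignError", "GroundTruth", "EpochedDataset",
    "ROIPattern", "ROIPatternSet",
    "generate_design", "generate_subject_epochs", "generate_fmri_patterns",
    "generate_roi_pattern_set",
]

EPOCH_START_MS = -100.0
EPOCH_END_MS = 5000.0
CUE_ONSET_MS = 0.0
STIMULUS_ONSET_MS = 2000.0
RESPONSE_SCREEN_MS = 3500.0

TASK_NAMES = ("color", "tilt", "content", "size")
PERCEPTUAL_TASKS = (0, 1)
CONCEPTUAL_TASKS = (2, 3)


class DesignError(ValueError):
    """Inconsistent factorial design arithmetic."""


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design parameters.

    The default design has 8 x 5 x 2 x 2 = 160 unique stimuli, each shown
    once per task (640 experimental trials), in 20 runs of 36 trials
    (32 experimental + 4 catch).
    """

    n_tasks: int = 4
    n_categories: int = 8
    n_exemplars: int = 5
    n_colors: int = 2
    n_tilts: int = 2
    n_runs: int = 20
    trials_per_run: int = 36
    catch_per_run: int = 4

    def __post_init__(self) -> None:
        for name in ("n_tasks", "n_categories", "n_exemplars", "n_colors",
                     "n_tilts", "n_runs", "trials_per_run"):
            if getattr(self, name) < 1:
                raise DesignError(f"{name} must be >= 1")
        if self.catch_per_run < 0 or self.catch_per_run >= self.trials_per_run:
            raise DesignError("catch_per_run must be in [0, trials_per_run)")

    @property
    def experimental_per_run(self) -> int:
        return self.trials_per_run - self.catch_per_run

    @property
    def n_unique_stimuli(self) -> int:
        return self.n_categories * self.n_exemplars * self.n_colors * self.n_tilts

    @property
    def n_experimental(self) -> int:
        return self.n_unique_stimuli * self.n_tasks

    @property
    def n_catch(self) -> int:
        return self.n_runs * self.catch_per_run

    def validate_run_arithmetic(self) -> None:
        if self.n_runs * self.experimental_per_run != self.n_experimental:
            raise DesignError(
                f"runs x experimental trials per run "
                f"({self.n_runs} x {self.experimental_per_run}) does not equal "
                f"unique stimuli x tasks ({self.n_unique_stimuli} x {self.n_tasks})")


TRIAL_COLUMNS = ["task", "category", "exemplar", "color", "tilt", "run", "is_catch"]


def generate_design(spec: DesignSpec, seed: int) -> pd.DataFrame:
    """Randomized trial table for one subject.

    Returns a DataFrame with one row per trial and columns ``task``,
    ``category``, ``exemplar``, ``color``, ``tilt``, ``run``, ``is_catch``.
    Experimental rows enumerate every (category, exemplar, color, tilt)
    stimulus once per task; catch rows are random task/stimulus combinations.
    """
    spec.validate_run_arithmetic()
    rng = np.random.default_rng(seed)

    grids = np.meshgrid(
        np.arange(spec.n_tasks), np.arange(spec.n_categories),
        np.arange(spec.n_exemplars), np.arange(spec.n_colors),
        np.arange(spec.n_tilts), indexing="ij")
    exp = np.stack([g.ravel() for g in grids], axis=1)
    exp = exp[rng.permutation(exp.shape[0])]

    n_catch = spec.n_catch
    catch = np.stack([
        rng.integers(0, spec.n_tasks, n_catch),
        rng.integers(0, spec.n_categories, n_catch),
        rng.integers(0, spec.n_exemplars, n_catch),
        rng.integers(0, spec.n_colors, n_catch),
        rng.integers(0, spec.n_tilts, n_catch),
    ], axis=1) if n_catch else np.empty((0, 5), dtype=int)

    rows = []
    for run in range(spec.n_runs):
        e0 = run * spec.experimental_per_run
        c0 = run * spec.catch_per_run
        block_stim = np.concatenate(
            [exp[e0:e0 + spec.experimental_per_run],
             catch[c0:c0 + spec.catch_per_run]], axis=0)
        block_catch = np.concatenate(
            [np.zeros(spec.experimental_per_run, dtype=bool),
             np.ones(spec.catch_per_run, dtype=bool)])
        order = rng.permutation(block_stim.shape[0])
        for i in order:
            rows.append((*block_stim[i], run, bool(block_catch[i])))

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _smoothed_boxcar(t_ms: np.ndarray, onset_ms: float, offset_ms: float,
                     ramp_ms: float = 10.0) -> np.ndarray:
    """Boxcar with half-cosine rising/falling edges *starting at* the onset
    (no pre-onset energy)."""
    env = np.zeros_like(t_ms, dtype=float)
    rise = (t_ms >= onset_ms) & (t_ms < onset_ms + ramp_ms)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (t_ms[rise] - onset_ms) / ramp_ms))
    env[(t_ms >= onset_ms + ramp_ms) & (t_ms <= offset_ms)] = 1.0
    fall = (t_ms > offset_ms) & (t_ms < offset_ms + ramp_ms)
    env[fall] = 0.5 * (1 + np.cos(np.pi * (t_ms[fall] - offset_ms) / ramp_ms))
    return env


@dataclass
class GroundTruth:
    """Latent signal structure injected into synthetic epochs.

    Onsets are in ms relative to the cue (task) or to the stimulus (object).
    Amplitudes scale unit-norm spatial patterns against the sensor noise SD.
    ``task_envelope``/``object_envelope``, if given, are callables of the
    epoch time axis (ms relative to cue) returning nonnegative amplitude
    envelopes that override the default smoothed boxcars.
    """

    task_onset_ms: float = 100.0
    object_onset_ms: float = 80.0
    task_amplitude: float = 1.0
    object_amplitude: float = 1.0
    task_envelope: Callable[[np.ndarray], np.ndarray] | None = None
    object_envelope: Callable[[np.ndarray], np.ndarray] | None = None
    tasktype_gain: float = 1.0
    tasktype_gain_onset_ms: float = 0.0
    pattern_seed: int = 0

    def __post_init__(self) -> None:
        if self.task_amplitude < 0 or self.object_amplitude < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.tasktype_gain < 0:
            raise ValueError("tasktype_gain must be nonnegative")
        if not (EPOCH_START_MS <= CUE_ONSET_MS + self.task_onset_ms <= EPOCH_END_MS):
            raise ValueError("task onset outside the epoch")
        if not (EPOCH_START_MS <= STIMULUS_ONSET_MS + self.object_onset_ms <= EPOCH_END_MS):
            raise ValueError("object onset outside the epoch")

    def task_env(self, t_ms: np.ndarray) -> np.ndarray:
        if self.task_envelope is not None:
            env = np.asarray(self.task_envelope(t_ms), dtype=float)
        else:
            env = _smoothed_boxcar(t_ms, CUE_ONSET_MS + self.task_onset_ms,
                                   EPOCH_END_MS)
        if np.any(env < 0):
            raise ValueError("task envelope must be nonnegative")
        return self.task_amplitude * env

    def object_env(self, t_ms: np.ndarray) -> np.ndarray:
        if self.object_envelope is not None:
            env = np.asarray(self.object_envelope(t_ms), dtype=float)
        else:
            onset = STIMULUS_ONSET_MS + self.object_onset_ms
            env = _smoothed_boxcar(t_ms, onset, onset + 1000.0)
        if np.any(env < 0):
            raise ValueError("object envelope must be nonnegative")
        return self.object_amplitude * env


@dataclass
class EpochedDataset:
    """Epoched multichannel time series with per-trial labels.

    ``data`` has shape (n_trials, n_channels, n_times); ``time_ms`` is
    relative to cue onset, strictly increasing with uniform spacing
    1000 / sampling_rate.
    """

    data: np.ndarray
    time_ms: np.ndarray
    sampling_rate: float
    trials: pd.DataFrame
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if self.data.shape[0] != len(self.trials):
            raise ValueError("trial count mismatch between data and labels")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis length mismatch")
        dt = np.diff(self.time_ms)
        if not (np.all(dt > 0) and np.allclose(dt, 1000.0 / self.sampling_rate,
                                               rtol=1e-6, atol=1e-6)):
            raise ValueError("time axis must be uniform with spacing 1000/rate")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def epoch_time_axis(sampling_rate: float) -> np.ndarray:
    n = int(round((EPOCH_END_MS - EPOCH_START_MS) / 1000.0 * sampling_rate))
    return EPOCH_START_MS + np.arange(n) * 1000.0 / sampling_rate


def generate_subject_epochs(design: pd.DataFrame, truth: GroundTruth,
                            n_channels: int = 64, sampling_rate: float = 300.0,
                            noise_sd: float = 1.0, seed: int = 0,
                            subject_id: str | None = None) -> EpochedDataset:
    """Simulate one subject's epoched sensor data.

    Each trial is the sum of a task-specific spatial pattern weighted by the
    task envelope, a category-specific spatial pattern weighted by the object
    envelope (times the task-type gain on conceptual-task trials after the
    gain onset), and white Gaussian noise.  Spatial patterns are unit-norm
    and drawn once per subject from ``truth.pattern_seed``; the same
    ``(design, truth, seed)`` always yields bit-identical data.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    t_ms = epoch_time_axis(sampling_rate)
    n_t = t_ms.size
    n_trials = len(design)

    prng = np.random.default_rng(truth.pattern_seed)
    n_tasks = int(design["task"].max()) + 1
    n_cats = int(design["category"].max()) + 1
    task_patterns = prng.standard_normal((n_tasks, n_channels))
    task_patterns /= np.linalg.norm(task_patterns, axis=1, keepdims=True)
    cat_patterns = prng.standard_normal((n_cats, n_channels))
    cat_patterns /= np.linalg.norm(cat_patterns, axis=1, keepdims=True)

    task_env = truth.task_env(t_ms)
    obj_env = truth.object_env(t_ms)
    gain_step = np.where(
        t_ms >= STIMULUS_ONSET_MS + truth.tasktype_gain_onset_ms,
        truth.tasktype_gain, 1.0)

    tasks = np.asarray(design["task"])
    cats = np.asarray(design["category"])
    conceptual = np.isin(tasks, CONCEPTUAL_TASKS)

    # trial x channel x time signal in float32 (sensor data; the dynamic
    # range is tiny and the arrays are not)
    nrng = np.random.default_rng(seed)
    if noise_sd > 0:
        data = nrng.standard_normal((n_trials, n_channels, n_t),
                                    dtype=np.float32)
        data *= np.float32(noise_sd)
    else:
        data = np.zeros((n_trials, n_channels, n_t), dtype=np.float32)
    data += task_patterns.astype(np.float32)[tasks][:, :, None] \
        * task_env.astype(np.float32)[None, None, :]
    obj_envs = np.where(conceptual[:, None], obj_env[None, :] * gain_step[None, :],
                        obj_env[None, :]).astype(np.float32)
    data += cat_patterns.astype(np.float32)[cats][:, :, None] \
        * obj_envs[:, None, :]

    return EpochedDataset(data, t_ms, sampling_rate, design.reset_index(drop=True),
                          subject_id=subject_id or f"S{seed:02d}")


# ---------------------------------------------------------------------------
# fMRI-like ROI condition patterns


@dataclass
class ROIPattern:
    name: str
    patterns: np.ndarray  # (n_conditions, n_units)
    task_weight: float
    object_weight: float
    noise_sd: float


@dataclass
class ROIPatternSet:
    """Condition-by-unit activity patterns for one or more ROIs, plus the
    condition ordering (task-major) they share."""

    rois: dict[str, ROIPattern]
    condition_order: list[tuple[int, int]]

    def __post_init__(self) -> None:
        n = len(self.condition_order)
        for roi in self.rois.values():
            if roi.patterns.shape[0] != n:
                raise ValueError(f"ROI {roi.name}: expected {n} condition rows")
            if roi.patterns.shape[1] < 2:
                raise ValueError(f"ROI {roi.name}: needs >= 2 units")


def _structured_basis(rng: np.random.Generator, n_units: int, n_tasks: int,
                      n_categories: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean-zero orthonormal task and category basis vectors.

    Orthogonalizing against the constant vector makes within-level pattern
    correlations exactly 1 and between-level correlations exactly 0 in the
    noise-free case, so the induced 1 - r RDM reproduces the binary model
    RDMs exactly.  With too few units for orthogonalization, plain Gaussian
    vectors are used (approximate structure).
    """
    k = n_tasks + n_categories
    if n_units >= k + 1:
        m = np.column_stack([np.ones(n_units),
                             rng.standard_normal((n_units, k))])
        q, _ = np.linalg.qr(m)
        basis = q[:, 1:1 + k].T
    else:
        basis = rng.standard_normal((k, n_units))
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)
    # unit per-unit SD, so mixing weights and noise_sd share one scale
    basis = basis * np.sqrt(n_units)
    return basis[:n_tasks], basis[n_tasks:]


def generate_fmri_patterns(task_weight: float, object_weight: float,
                           noise_sd: float, n_units: int = 100, seed: int = 0,
                           n_tasks: int = 4, n_categories: int = 8,
                           roi_name: str = "ROI") -> ROIPatternSet:
    """Synthesize condition patterns for a single ROI.

    The pattern for condition (task t, category c) is
    ``task_weight * u_t + object_weight * v_c + noise_sd * eps`` with
    orthonormal mean-zero ``u``/``v``; the induced 1 - Pearson RDM then
    correlates with the task and category model RDMs in proportion to the
    squared weights.
    """
    if task_weight < 0 or object_weight < 0 or noise_sd < 0:
        raise ValueError("weights and noise_sd must be nonnegative")
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    rng = np.random.default_rng(seed)
    u, v = _structured_basis(rng, n_units, n_tasks, n_categories)
    order = task_major_conditions(n_tasks, n_categories)
    pats = np.empty((len(order), n_units))
    for i, (t, c) in enumerate(order):
        pats[i] = task_weight * u[t] + object_weight * v[c]
    if noise_sd > 0:
        pats += noise_sd * rng.standard_normal(pats.shape)
    roi = ROIPattern(roi_name, pats, task_weight, object_weight, noise_sd)
    return ROIPatternSet({roi_name: roi}, order)


def generate_roi_pattern_set(mixtures: dict[str, tuple[float, float, float]],
                             n_units: int = 100, seed: int = 0,
                             n_tasks: int = 4, n_categories: int = 8) -> ROIPatternSet:
    """Several ROIs with per-ROI (task_weight, object_weight, noise_sd)."""
    rois: dict[str, ROIPattern] = {}
    order = None
    for i, (name, (tw, ow, sd)) in enumerate(mixtures.items()):
        one = generate_fmri_patterns(tw, ow, sd, n_units=n_units,
                                     seed=seed + i, n_tasks=n_tasks,
                                     n_categories=n_categories, roi_name=name)
        rois[name] = one.rois[name]
        order = one.condition_order
    return ROIPatternSet(rois, order)
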