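"""Sensor-space preprocessing: band-pass + notch filtering, spatial PCA,
low-variance component pruning, baseline (univariate noise) normalization,
temporal smoothing and downsampling.

The canonical order is filter -> PCA -> drop -> normalize -> smooth ->
downsample; each stage is a pure function of its inputs and configuration.
The PCA is purely spatial (a rotation of the channel axis), so no stage
before smoothing mixes information across time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .synth import EpochedDataset

__all__ = [
    "PreprocessConfig", "PCAModel", "ComponentDataset",
    "filter_epochs", "fit_spatial_pca", "n_components_to_drop",
    "drop_low_variance_components", "baseline_normalize",
    "smooth_and_downsample", "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    ``band_hz`` defaults to 0.1-300 Hz with a 60 Hz notch (plus harmonics
    below Nyquist), matching typical 1200 Hz MEG recordings; for lower
    sampling rates the upper band edge must be brought below Nyquist.
    ``baseline_task_ms`` (-100..0, pre-cue) is used when decoding task,
    ``baseline_object_ms`` (1900..2000, pre-stimulus) when decoding object
    category.  ``smooth_hdhm_ms`` is the Gaussian kernel's half duration at
    half maximum (full width at half maximum = twice this).
    """

    band_hz: tuple[float, float] = (0.1, 300.0)
    notch_hz: float = 60.0
    variance_drop_fraction: float = 0.01
    max_drop_fraction: float = 0.5
    baseline_task_ms: tuple[float, float] = (-100.0, 0.0)
    baseline_object_ms: tuple[float, float] = (1900.0, 2000.0)
    smooth_hdhm_ms: float = 15.0
    target_rate_hz: float = 120.0

    def __post_init__(self) -> None:
        if not 0 < self.variance_drop_fraction < 1:
            raise ValueError("variance_drop_fraction must be in (0, 1)")
        if not 0 < self.max_drop_fraction <= 1:
            raise ValueError("max_drop_fraction must be in (0, 1]")
        if self.band_hz[0] >= self.band_hz[1]:
            raise ValueError("band edges must be increasing")
        if self.band_hz[0] < 0:
            raise ValueError("band edges must be nonnegative")

    def baseline_ms(self, factor: str) -> tuple[float, float]:
        if factor == "task":
            return self.baseline_task_ms
        if factor == "category":
            return self.baseline_object_ms
        raise ValueError(f"unknown factor {factor!r}")


@dataclass
class PCAModel:
    """Spatial PCA fit: channel loadings, component variances, fit metadata."""

    components: np.ndarray      # (n_channels, n_components), orthonormal columns
    variances: np.ndarray       # descending
    mean: np.ndarray            # per-channel mean over all trials and samples
    n_trials: int
    n_samples: int


@dataclass
class ComponentDataset:
    """Trials x components x times scores, with provenance of how they were
    produced (PCA variances, baseline window, smoothing, rates)."""

    data: np.ndarray
    time_ms: np.ndarray
    sampling_rate: float
    trials: pd.DataFrame
    subject_id: str = "S00"
    provenance: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


def filter_epochs(epochs: EpochedDataset, config: PreprocessConfig) -> EpochedDataset:
    """Zero-phase band-pass plus line-noise notch (fundamental + harmonics
    below Nyquist).  Shape is preserved."""
    fs = epochs.sampling_rate
    nyq = fs / 2.0
    lo, hi = config.band_hz
    if hi >= nyq:
        raise ValueError(f"upper band edge {hi} Hz >= Nyquist {nyq} Hz")
    # high-pass and low-pass designed separately: a single wide band-pass
    # design (e.g. 0.1-200 Hz) is numerically ill-conditioned.
    # lo = 0 disables the high-pass edge: on epoch-length data a zero-phase
    # high-pass redistributes sustained responses into the baseline, so
    # drift-free (synthetic) data is low-passed only.
    sections = [signal.butter(4, hi, btype="lowpass", fs=fs, output="sos")]
    if lo > 0:
        sections.append(signal.butter(4, lo, btype="highpass", fs=fs,
                                      output="sos"))
    f = config.notch_hz
    while f < nyq:
        b, a = signal.iirnotch(f, Q=30.0, fs=fs)
        sections.append(np.hstack([b, a])[None, :])
        f += config.notch_hz
    sos = np.vstack(sections)
    # even padding, long enough for the slowest transient (the high-pass
    # edge, or the ~2 Hz-wide notch when there is no high-pass); the scipy
    # default padding is far too short for sub-Hz edges
    n_t = epochs.data.shape[-1]
    slowest_hz = lo if lo > 0 else config.notch_hz / 30.0
    padlen = min(n_t - 2, int(3.0 * fs / slowest_hz))
    # trial-chunked to bound the filtfilt working set on large epochs
    out = np.empty(epochs.data.shape, dtype=np.float64)
    for i in range(0, epochs.data.shape[0], 64):
        out[i:i + 64] = signal.sosfiltfilt(sos, epochs.data[i:i + 64],
                                           axis=-1, padtype="even",
                                           padlen=padlen)
    return EpochedDataset(np.ascontiguousarray(out), epochs.time_ms.copy(),
                          fs, epochs.trials, subject_id=epochs.subject_id)


def fit_spatial_pca(epochs: EpochedDataset) -> tuple[PCAModel, ComponentDataset]:
    """Spatial PCA over channels, fit on all trials concatenated in time.

    The rotation is purely spatial: each output sample depends only on the
    same input sample.  Component scores have diagonal covariance and the
    total variance about the fit mean is conserved.
    """
    n_trials, n_ch, n_t = epochs.data.shape
    if n_ch < 2 or n_trials * n_t < 2:
        raise ValueError("need >= 2 channels and >= 2 total samples")
    if not np.all(np.isfinite(epochs.data)):
        raise ValueError("non-finite data")
    n = n_trials * n_t
    mu = epochs.data.mean(axis=(0, 2), dtype=np.float64)
    # covariance via the channel Gram matrix, accumulated per trial
    # (no centered or transposed copy of the full data)
    gram = np.matmul(epochs.data,
                     epochs.data.transpose(0, 2, 1)).sum(axis=0)
    cov = (gram - n * np.outer(mu, mu)) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    variances = np.maximum(eigval[order], 0.0)
    w = eigvec[:, order]
    model = PCAModel(components=w, variances=variances, mean=mu,
                     n_trials=n_trials, n_samples=n)
    # scores in float32: single-precision is ample for component time
    # courses and halves the decoding working set
    w32 = w.astype(np.float32)
    comp = np.matmul(w32.T[None, :, :],
                     np.ascontiguousarray(epochs.data, dtype=np.float32))
    comp -= (mu @ w).astype(np.float32)[None, :, None]
    ds = ComponentDataset(np.ascontiguousarray(comp), epochs.time_ms.copy(),
                          epochs.sampling_rate, epochs.trials,
                          subject_id=epochs.subject_id,
                          provenance={"pca_variances": model.variances.tolist()})
    return model, ds


def n_components_to_drop(variances: np.ndarray, variance_drop_fraction: float = 0.01,
                         max_drop_fraction: float = 0.5) -> int:
    """Size of the removable low-variance suffix.

    Removes the largest ascending-variance suffix whose summed variance is
    at most ``variance_drop_fraction`` of the total; if that suffix would
    exceed ``max_drop_fraction`` of the components, exactly
    ``floor(max_drop_fraction * n)`` are removed instead.
    """
    v = np.sort(np.asarray(variances, dtype=float))
    total = v.sum()
    if total <= 0:
        return 0
    # small relative tolerance so exact-boundary suffixes are not lost to
    # floating-point accumulation
    thresh = variance_drop_fraction * total * (1 + 1e-9)
    k = int(np.searchsorted(np.cumsum(v), thresh, side="right"))
    cap = math.floor(max_drop_fraction * v.size)
    return min(k, cap)


def drop_low_variance_components(data: ComponentDataset, model: PCAModel,
                                 variance_drop_fraction: float = 0.01,
                                 max_drop_fraction: float = 0.5) -> ComponentDataset:
    """Prune the lowest-variance PCA components (see n_components_to_drop)."""
    n_drop = n_components_to_drop(model.variances, variance_drop_fraction,
                                  max_drop_fraction)
    keep = data.n_components - n_drop
    prov = dict(data.provenance)
    prov.update(n_dropped_components=n_drop,
                variance_drop_fraction=variance_drop_fraction,
                max_drop_fraction=max_drop_fraction)
    return ComponentDataset(data.data[:, :keep, :].copy(), data.time_ms.copy(),
                            data.sampling_rate, data.trials,
                            subject_id=data.subject_id, provenance=prov)


def baseline_normalize(data: ComponentDataset,
                       window_ms: tuple[float, float]) -> ComponentDataset:
    """Univariate noise normalization against a baseline window.

    Per component, the mean and SD over all trials' baseline samples
    (pooled) are computed; every sample becomes (x - mean) / SD.
    """
    t = data.time_ms
    mask = (t >= window_ms[0]) & (t < window_ms[1])
    if mask.sum() < 2:
        raise ValueError("baseline window must contain >= 2 samples")
    base = data.data[:, :, mask]                      # (trials, comps, nb)
    mu = base.mean(axis=(0, 2), dtype=np.float64)
    sd = base.std(axis=(0, 2), dtype=np.float64)
    # constant components leave rounding residue, not an exact zero SD
    zero = np.nonzero(sd <= 1e-10 * np.maximum(1.0, np.abs(mu)))[0]
    if zero.size:
        raise ValueError(f"component {int(zero[0])} has zero baseline SD")
    out = (data.data - mu[None, :, None].astype(data.data.dtype)) \
        / sd[None, :, None].astype(data.data.dtype)
    prov = dict(data.provenance)
    prov["baseline_window_ms"] = list(window_ms)
    return ComponentDataset(out, t.copy(), data.sampling_rate, data.trials,
                            subject_id=data.subject_id, provenance=prov)


def smooth_and_downsample(data: ComponentDataset, hdhm_ms: float = 15.0,
                          target_rate_hz: float = 120.0) -> ComponentDataset:
    """Gaussian temporal smoothing followed by integer-ratio decimation.

    The kernel's full width at half maximum is ``2 * hdhm_ms`` (sigma =
    2*hdhm / (2*sqrt(2 ln 2))), unit sum, truncated at +/-4 sigma with
    reflected edges.  Decimation keeps every (rate ratio)-th smoothed sample
    starting at the epoch start; non-integer ratios are an error.
    """
    if hdhm_ms <= 0:
        raise ValueError("hdhm_ms must be > 0")
    fs = data.sampling_rate
    if target_rate_hz > fs:
        raise ValueError("target rate exceeds current rate")
    ratio_f = fs / target_rate_hz
    ratio = int(round(ratio_f))
    if abs(ratio_f - ratio) > 1e-9:
        raise ValueError(f"rate ratio {ratio_f} is not an integer")
    sigma_ms = 2.0 * hdhm_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sigma_samples = sigma_ms * fs / 1000.0
    sm = gaussian_filter1d(data.data, sigma_samples, axis=-1, mode="reflect",
                           truncate=4.0)
    out = np.ascontiguousarray(sm[:, :, ::ratio])
    prov = dict(data.provenance)
    prov.update(smooth_hdhm_ms=hdhm_ms, source_rate_hz=fs,
                target_rate_hz=target_rate_hz)
    return ComponentDataset(out, data.time_ms[::ratio].copy(), target_rate_hz,
                            data.trials, subject_id=data.subject_id,
                            provenance=prov)


def preprocess(epochs: EpochedDataset, config: PreprocessConfig,
               factor: str = "task") -> ComponentDataset:
    """Full chain: filter -> PCA -> drop -> normalize (factor-specific
    baseline) -> smooth -> downsample.  Records the factor in provenance."""
    filtered = filter_epochs(epochs, config)
    model, comp = fit_spatial_pca(filtered)
    comp = drop_low_variance_components(comp, model,
                                        config.variance_drop_fraction,
                                        config.max_drop_fraction)
    comp = baseline_normalize(comp, config.baseline_ms(factor))
    comp = smooth_and_downsample(comp, config.smooth_hdhm_ms,
                                 config.target_rate_hz)
    comp.provenance["baseline_factor"] = factor
    return comp
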