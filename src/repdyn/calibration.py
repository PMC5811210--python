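"""Calibration runs on structureless data.

The decoding pipeline's most basic correctness property is that data with
no condition-specific structure decodes at the 50% chance level.  This
module runs that end-to-end check: pure-noise subjects (all signal
amplitudes zero, unit Gaussian sensor noise) are pushed through filtering,
spatial PCA, component pruning, baseline normalization, smoothing,
downsampling and object-category decoding, and the grand mean accuracy over
time, pairs and subjects is returned.
"""

from __future__ import annotations

import numpy as np

from .decoding import DecodingConfig, decode_timecourse
from .pipeline import PipelineConfig, _preproc_config
from .preprocess import (baseline_normalize, drop_low_variance_components,
                         filter_epochs, fit_spatial_pca, smooth_and_downsample)
from .synth import DesignSpec, GroundTruth, generate_design, generate_subject_epochs

__all__ = ["noise_decoding_accuracy"]


def noise_decoding_accuracy(n_subjects: int = 10, n_iterations: int = 50,
                            n_channels: int = 64, sampling_rate: float = 300.0,
                            seed: int = 1) -> float:
    """Grand-mean object-category decoding accuracy (%) on pure noise.

    Subject s uses seed ``seed + s`` for both design and noise; the
    expected value is the 50% chance level.
    """
    pp = _preproc_config(PipelineConfig().preprocess)
    truth = GroundTruth(task_amplitude=0.0, object_amplitude=0.0,
                        pattern_seed=0)
    means = []
    for s in range(n_subjects):
        design = generate_design(DesignSpec(), seed + s)
        epochs = generate_subject_epochs(design, truth, n_channels=n_channels,
                                         sampling_rate=sampling_rate,
                                         noise_sd=1.0, seed=seed + s)
        filtered = filter_epochs(epochs, pp)
        model, comp = fit_spatial_pca(filtered)
        comp = drop_low_variance_components(comp, model,
                                            pp.variance_drop_fraction,
                                            pp.max_drop_fraction)
        comp = baseline_normalize(comp, pp.baseline_ms("category"))
        comp = smooth_and_downsample(comp, pp.smooth_hdhm_ms,
                                     pp.target_rate_hz)
        comp.provenance["baseline_factor"] = "category"
        cfg = DecodingConfig(label_factor="category",
                             n_iterations=n_iterations, seed=seed + s)
        means.append(decode_timecourse(comp, cfg).accuracy.mean())
    return float(np.mean(means))
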