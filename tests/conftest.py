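import numpy as np
import pandas as pd
import pytest

from repdyn import DesignSpec, GroundTruth, generate_design, generate_subject_epochs
from repdyn.preprocess import ComponentDataset


@pytest.fixture(scope="session")
def default_design() -> pd.DataFrame:
    return generate_design(DesignSpec(), seed=123)


@pytest.fixture(scope="session")
def small_epochs():
    """Low-rate, few-channel epochs with default signal structure."""
    design = generate_design(DesignSpec(), seed=7)
    truth = GroundTruth(pattern_seed=1)
    return generate_subject_epochs(design, truth, n_channels=12,
                                   sampling_rate=60.0, noise_sd=1.0, seed=7)


def make_component_dataset(data, rate=100.0, trials=None, factor=None,
                           t0=-100.0):
    """Wrap a raw (trials, features, times) array as a ComponentDataset."""
    data = np.asarray(data)
    n_trials, _, n_t = data.shape
    if trials is None:
        rng = np.random.default_rng(0)
        trials = pd.DataFrame({
            "task": rng.integers(0, 4, n_trials),
            "category": rng.integers(0, 8, n_trials),
            "is_catch": np.zeros(n_trials, dtype=bool),
        })
    prov = {} if factor is None else {"baseline_factor": factor}
    return ComponentDataset(data, t0 + np.arange(n_t) * 1000.0 / rate, rate,
                            trials, provenance=prov)


def labeled_noise_dataset(rng, n_per_class, classes, n_feat, n_t, rate=100.0,
                          factor="category"):
    """Noise dataset with balanced class labels (single factor)."""
    labels = np.repeat(classes, n_per_class)
    rng.shuffle(labels)
    data = rng.standard_normal((labels.size, n_feat, n_t)).astype(np.float32)
    trials = pd.DataFrame({factor: labels,
                           "is_catch": np.zeros(labels.size, dtype=bool)})
    if factor != "task":
        trials["task"] = rng.integers(0, 4, labels.size)
    return make_component_dataset(data, rate=rate, trials=trials,
                                  factor=factor)
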