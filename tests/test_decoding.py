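"""Supertrial construction, ordering accuracy, and the decoding analyses."""

import numpy as np
import pandas as pd
import pytest

from repdyn import (DecodingConfig, cross_tasktype_object_decode,
                    decode_timecourse, make_supertrials, ordering_accuracy,
                    temporal_generalization)

from conftest import labeled_noise_dataset, make_component_dataset


def _class_dataset(patterns, n_per_class, n_t=20, noise=0.0, seed=0,
                   factor="category"):
    """Constant class patterns (n_classes, d) held over the whole epoch."""
    rng = np.random.default_rng(seed)
    n_classes, d = patterns.shape
    labels = np.repeat(np.arange(n_classes), n_per_class)
    data = patterns[labels][:, :, None] * np.ones(n_t)
    if noise:
        data = data + noise * rng.standard_normal(data.shape)
    trials = pd.DataFrame({factor: labels,
                           "is_catch": np.zeros(labels.size, bool)})
    return make_component_dataset(data.astype(np.float32), trials=trials,
                                  factor=factor)


class TestSupertrials:
    def test_exact_partition(self):
        ds = labeled_noise_dataset(np.random.default_rng(0), 40, [0, 1], 4, 10)
        sup = make_supertrials(ds, "category", 10, rng_seed=1)
        for cls in (0, 1):
            assert sup.supertrials[cls].shape == (4, 4, 10)
            used = np.concatenate(sup.mapping[cls])
            assert len(used) == len(set(used)) == 40

    def test_remainder_trials_unused(self):
        rng = np.random.default_rng(1)
        ds = labeled_noise_dataset(rng, 43, [0, 1], 3, 5)
        sup = make_supertrials(ds, "category", 10, rng_seed=2)
        assert sup.supertrials[0].shape[0] == 4
        assert sum(len(g) for g in sup.mapping[0]) == 40

    def test_identical_trials_average_to_the_trial(self):
        pattern = np.arange(12, dtype=np.float32).reshape(3, 4)
        data = np.broadcast_to(pattern, (20, 3, 4)).copy()
        trials = pd.DataFrame({"category": np.zeros(20, int),
                               "is_catch": np.zeros(20, bool)})
        ds = make_component_dataset(data, trials=trials)
        sup = make_supertrials(ds, "category", 10, rng_seed=0)
        assert np.allclose(sup.supertrials[0], pattern[None], atol=1e-6)

    def test_insufficient_trials_error(self):
        ds = labeled_noise_dataset(np.random.default_rng(2), 5, [0, 1], 3, 5)
        with pytest.raises(ValueError, match="need >= 10"):
            make_supertrials(ds, "category", 10, rng_seed=0)


class TestOrderingAccuracy:
    @pytest.mark.parametrize("dv,expected", [((0.7, -0.2), 100.0),
                                             ((-0.2, 0.7), 0.0),
                                             ((0.3, 0.3), 50.0)])
    def test_examples(self, dv, expected):
        assert ordering_accuracy(dv, ("A", "B")) == expected

    def test_equals_two_sample_auc_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(2000):
            dv = rng.standard_normal(2)
            # brute-force two-sample AUC: rank comparison of the one
            # positive-class score against the one negative-class score
            auc = 100.0 * ((dv[0] > dv[1]) + 0.5 * (dv[0] == dv[1]))
            assert ordering_accuracy(dv, ("A", "B")) == auc

    def test_bias_independent(self):
        dv = (0.2, -0.1)
        shifted = (dv[0] + 5.0, dv[1] + 5.0)
        assert ordering_accuracy(dv, (0, 1)) == ordering_accuracy(shifted, (0, 1))


class TestDecodeTimecourse:
    def test_separable_patterns_decode_perfectly(self):
        patterns = 3.0 * np.eye(4, 6, dtype=np.float32)
        ds = _class_dataset(patterns, n_per_class=20, noise=0.3)
        cfg = DecodingConfig(label_factor="category", supertrial_size=5,
                             n_iterations=3, seed=0)
        tc = decode_timecourse(ds, cfg)
        assert np.all(tc.accuracy == 100.0)

    def test_noise_is_at_chance(self):
        ds = labeled_noise_dataset(np.random.default_rng(4), 40,
                                   list(range(4)), 8, 30)
        cfg = DecodingConfig(label_factor="category", n_iterations=20, seed=1)
        tc = decode_timecourse(ds, cfg)
        # SE of the time-mean over 30 points x 6 pairs x 20 iterations
        assert tc.accuracy.mean() == pytest.approx(50.0, abs=3.0)
        assert tc.chance == 50.0

    def test_no_temporal_leakage(self):
        """Shuffling every other time point leaves the curve at t unchanged."""
        rng = np.random.default_rng(5)
        ds = labeled_noise_dataset(rng, 20, [0, 1], 5, 12)
        cfg = DecodingConfig(label_factor="category", supertrial_size=10,
                             n_iterations=4, seed=2)
        ref = decode_timecourse(ds, cfg).accuracy[6]
        shuffled = ds.data.copy()
        other = [t for t in range(12) if t != 6]
        shuffled[:, :, other] = rng.permutation(shuffled[:, :, other], axis=0)
        ds2 = make_component_dataset(shuffled, trials=ds.trials,
                                     factor="category")
        assert decode_timecourse(ds2, cfg).accuracy[6] == ref

    def test_provenance_factor_mismatch_rejected(self):
        ds = labeled_noise_dataset(np.random.default_rng(6), 10, [0, 1], 3, 5,
                                   factor="category")
        ds.provenance["baseline_factor"] = "task"
        with pytest.raises(ValueError, match="baseline-normalized"):
            decode_timecourse(ds, DecodingConfig(label_factor="category",
                                                 supertrial_size=5,
                                                 n_iterations=1))

    def test_iteration_averaging_reduces_monte_carlo_noise(self):
        rng = np.random.default_rng(7)
        ds = labeled_noise_dataset(rng, 40, [0, 1], 6, 40)

        def curve_sd(n_it, seed):
            cfg = DecodingConfig(label_factor="category", n_iterations=n_it,
                                 seed=seed)
            return decode_timecourse(ds, cfg).accuracy

        few = np.std([curve_sd(4, s) for s in range(6)], axis=0).mean()
        many = np.std([curve_sd(16, s + 10) for s in range(6)], axis=0).mean()
        # 4x the iterations should roughly halve the Monte-Carlo SD
        assert many < few * 0.75


class TestCrossTaskType:
    def _tasked_dataset(self, pattern_by_type, n_per_cell=10, n_t=8,
                        noise=0.2, seed=0):
        """pattern_by_type[(type, category)] -> feature vector."""
        rng = np.random.default_rng(seed)
        rows, chunks = [], []
        for task in range(4):
            ttype = 0 if task in (0, 1) else 1
            for cat in (0, 1):
                p = pattern_by_type[(ttype, cat)]
                block = np.tile(p[None, :, None], (n_per_cell, 1, n_t))
                chunks.append(block + noise * rng.standard_normal(block.shape))
                rows += [(task, cat)] * n_per_cell
        trials = pd.DataFrame(rows, columns=["task", "category"])
        trials["is_catch"] = False
        return make_component_dataset(
            np.concatenate(chunks).astype(np.float32), trials=trials,
            factor="category")

    def test_identical_patterns_within_equals_between(self):
        pa, pb = 2.0 * np.eye(2, 6, dtype=float)
        ds = self._tasked_dataset({(0, 0): pa, (0, 1): pb,
                                   (1, 0): pa, (1, 1): pb})
        cfg = DecodingConfig(label_factor="category", supertrial_size=5,
                             n_iterations=10, seed=0)
        within, between = cross_tasktype_object_decode(ds, cfg)
        assert within.accuracy.mean() == pytest.approx(
            between.accuracy.mean(), abs=5.0)
        assert within.accuracy.mean() > 90.0

    def test_orthogonal_patterns_between_at_chance(self):
        e = 2.5 * np.eye(4, 8, dtype=float)
        ds = self._tasked_dataset({(0, 0): e[0], (0, 1): e[1],
                                   (1, 0): e[2], (1, 1): e[3]})
        cfg = DecodingConfig(label_factor="category", supertrial_size=5,
                             n_iterations=20, seed=1)
        within, between = cross_tasktype_object_decode(ds, cfg)
        assert within.accuracy.mean() > 90.0
        assert between.accuracy.mean() == pytest.approx(50.0, abs=10.0)

    def test_gain_difference_keeps_between_high(self):
        pa, pb = 2.0 * np.eye(2, 6, dtype=float)
        ds = self._tasked_dataset({(0, 0): pa, (0, 1): pb,
                                   (1, 0): 2.0 * pa, (1, 1): 2.0 * pb})
        cfg = DecodingConfig(label_factor="category", supertrial_size=5,
                             n_iterations=10, seed=2)
        within, between = cross_tasktype_object_decode(ds, cfg)
        assert within.accuracy.mean() > 90.0
        assert between.accuracy.mean() > 90.0


class TestTemporalGeneralization:
    def test_constant_pattern_generalizes_everywhere(self):
        patterns = 3.0 * np.eye(2, 5, dtype=np.float32)
        ds = _class_dataset(patterns, n_per_class=20, n_t=10, noise=0.3)
        cfg = DecodingConfig(label_factor="category", supertrial_size=5,
                             n_iterations=3, seed=0)
        tg = temporal_generalization(ds, cfg)
        assert np.all(tg.accuracy > 95.0)

    def test_orthogonal_epochs_give_block_structure(self):
        rng = np.random.default_rng(8)
        n_t = 12
        p1 = 3.0 * np.eye(2, 8)
        p2 = 3.0 * np.eye(2, 8, k=4)
        labels = np.repeat([0, 1], 30)
        data = np.zeros((60, 8, n_t))
        data[:, :, :6] = p1[labels][:, :, None]
        data[:, :, 6:] = p2[labels][:, :, None]
        data += 0.3 * rng.standard_normal(data.shape)
        trials = pd.DataFrame({"category": labels,
                               "is_catch": np.zeros(60, bool)})
        ds = make_component_dataset(data.astype(np.float32), trials=trials,
                                    factor="category")
        cfg = DecodingConfig(label_factor="category", supertrial_size=5,
                             n_iterations=6, seed=0)
        tg = temporal_generalization(ds, cfg)
        assert tg.accuracy[:6, :6].mean() > 95.0
        assert tg.accuracy[6:, 6:].mean() > 95.0
        assert abs(tg.accuracy[:6, 6:].mean() - 50.0) < 12.0
        assert abs(tg.accuracy[6:, :6].mean() - 50.0) < 12.0

    def test_diagonal_consistent_with_timecourse(self):
        rng = np.random.default_rng(9)
        patterns = 1.5 * np.eye(2, 6, dtype=np.float32)
        ds = _class_dataset(patterns, n_per_class=20, n_t=8, noise=1.0, seed=3)
        cfg = DecodingConfig(label_factor="category", supertrial_size=5,
                             n_iterations=10, seed=4)
        tg = temporal_generalization(ds, cfg)
        tc = decode_timecourse(ds, cfg)
        assert np.allclose(np.diag(tg.accuracy), tc.accuracy, atol=1e-9)
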