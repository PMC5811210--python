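"""Cluster-based permutation inference and bootstrap latency intervals."""

import numpy as np
import pytest

from repdyn import (bootstrap_peak_ci, cluster_2d, compute_rdm,
                    generate_roi_pattern_set, model_rdm,
                    rdm_randomization_cluster, sign_permutation_cluster_1d,
                    task_major_conditions)
from repdyn.rsa import RDM
from repdyn.stats import _all_signs, _max_run_lengths

ORDER = task_major_conditions(4, 8)


class TestSignPermutation1D:
    def test_exhaustive_enumeration_count_at_17_subjects(self):
        signs = _all_signs(17)
        assert signs.shape == (131072, 17)
        assert len({tuple(r) for r in signs[:1000]}) == 1000  # distinct

    def test_null_data_gives_no_significant_clusters(self):
        rng = np.random.default_rng(0)
        curves = rng.standard_normal((12, 40))
        res = sign_permutation_cluster_1d(curves, 0.0, seed=1)
        assert not res.significant_clusters

    def test_effect_window_recovered(self):
        rng = np.random.default_rng(1)
        curves = rng.standard_normal((12, 60)) * 0.5
        curves[:, 20:35] += 3.0
        res = sign_permutation_cluster_1d(curves, 0.0, seed=2)
        sig = res.significant_clusters
        assert len(sig) == 1
        assert sig[0].indices[0] in range(18, 23)
        assert sig[0].indices[-1] in range(32, 37)

    def test_p_values_never_zero(self):
        curves = np.abs(np.random.default_rng(2).standard_normal((8, 20))) + 5
        res = sign_permutation_cluster_1d(curves, 0.0, seed=3)
        assert res.clusters
        assert all(c.p_value > 0 for c in res.clusters)

    def test_chance_subtraction_and_mask(self):
        rng = np.random.default_rng(3)
        curves = 50.0 + rng.standard_normal((10, 30))
        curves[:, 5:25] += 4.0
        mask = np.zeros(30, bool)
        mask[10:] = True
        res = sign_permutation_cluster_1d(curves, 50.0, seed=4,
                                          time_mask=mask)
        assert res.significant_clusters
        assert min(res.significant_clusters[0].indices) >= 10

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            sign_permutation_cluster_1d(np.zeros((1, 10)), 0.0)

    def test_max_run_lengths_oracle(self):
        rng = np.random.default_rng(4)
        b = rng.random((50, 23)) < 0.4

        def brute(row):
            best = cur = 0
            for v in row:
                cur = cur + 1 if v else 0
                best = max(best, cur)
            return best

        assert np.array_equal(_max_run_lengths(b),
                              [brute(r) for r in b])


class TestCluster2D:
    def test_block_effect_recovered(self):
        rng = np.random.default_rng(5)
        mats = rng.standard_normal((10, 14, 14))
        mats[:, 4:9, 4:9] += 3.0
        res = cluster_2d(mats, 0.0, n_perm=512, seed=6)
        sig = res.significant_clusters
        assert len(sig) == 1
        idx = np.array(sig[0].indices)
        assert 20 <= sig[0].size <= 40  # ~the 25-point block
        assert idx.min() >= 2 and idx.max() <= 10

    def test_four_connectivity_splits_diagonal_touch(self):
        # two diagonally-touching supra-threshold points must form two
        # clusters under 4-connectivity
        n = 8
        mats = np.zeros((n, 6, 6))
        mats[:, 2, 2] = 10.0
        mats[:, 3, 3] = 10.0
        mats += 0.01 * np.random.default_rng(7).standard_normal(mats.shape)
        res = cluster_2d(mats, 0.0, n_perm=128, seed=8)
        holds_22 = [c for c in res.clusters if (2, 2) in c.indices]
        holds_33 = [c for c in res.clusters if (3, 3) in c.indices]
        assert holds_22 and holds_33
        assert holds_22[0] is not holds_33[0]

    def test_too_many_permutations_rejected(self):
        mats = np.zeros((4, 5, 5))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_2d(mats, 0.0, n_perm=100, seed=0)

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(9)
        hits = 0
        n_sim = 60
        for s in range(n_sim):
            mats = rng.standard_normal((10, 12, 12))
            res = cluster_2d(mats, 0.0, n_perm=256, seed=100 + s)
            hits += bool(res.significant_clusters)
        assert hits / n_sim < 0.15  # ~5% nominal, small-sample slack


class TestRDMRandomization:
    def _inputs(self, n_t=20, window=(8, 14), seed=0):
        rng = np.random.default_rng(seed)
        tm = model_rdm("task", ORDER)
        series = []
        for ti in range(n_t):
            base = 0.7 * tm.values + 0.2 if window[0] <= ti < window[1] \
                else np.full((32, 32), 0.5)
            m = base + 0.05 * rng.standard_normal((32, 32))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            series.append(RDM(m, ORDER, label=float(ti)))
        rois = generate_roi_pattern_set({"PFC": (1.0, 0.2, 0.3),
                                         "pFS": (0.2, 1.0, 0.3)}, seed=1)
        fmri = {n: compute_rdm(p.patterns, ORDER, label=n)
                for n, p in rois.rois.items()}
        return series, fmri, tm, model_rdm("category", ORDER)

    def test_permutation_preserves_symmetry_and_diagonal(self):
        series, *_ = self._inputs()
        perm = np.random.default_rng(2).permutation(32)
        p = series[0].values[perm][:, perm]
        assert np.allclose(p, p.T)
        assert np.all(np.diag(p) == 0)

    def test_identity_permutation_reproduces_observed(self):
        series, fmri, tm, cm = self._inputs()
        from repdyn.fusion import run_fusion
        obs = run_fusion(series, fmri, tm, cm)
        res = rdm_randomization_cluster(series, fmri, tm, cm, n_perm=10,
                                        seed=3)
        assert np.allclose(res["PFC"].observed_stat, obs.c_task["PFC"],
                           atol=1e-12)

    def test_task_window_detected_in_task_roi(self):
        series, fmri, tm, cm = self._inputs()
        res = rdm_randomization_cluster(series, fmri, tm, cm, n_perm=200,
                                        seed=4)
        sig = res["PFC"].significant_clusters
        assert sig and sig[0].indices[0] in range(6, 10)

    def test_structureless_series_rarely_significant(self):
        rng = np.random.default_rng(5)
        _, fmri, tm, cm = self._inputs()
        hits = 0
        for s in range(25):
            series = []
            for ti in range(15):
                m = 0.5 + 0.05 * rng.standard_normal((32, 32))
                m = (m + m.T) / 2
                np.fill_diagonal(m, 0)
                series.append(RDM(m, ORDER, label=float(ti)))
            res = rdm_randomization_cluster(series, fmri, tm, cm,
                                            n_perm=150, seed=200 + s)
            hits += any(r.significant_clusters for r in res.values())
        assert hits / 25 <= 0.2


class TestBootstrapPeakCI:
    def test_identical_subjects_zero_width(self):
        t = np.linspace(0, 500, 51)
        curve = np.exp(-((t - 200) / 50) ** 2)
        data = np.tile(curve, (6, 1))
        ci = bootstrap_peak_ci(data, t, (0, 500), n_boot=200, seed=0)
        assert ci.estimate_ms == ci.ci_low_ms == ci.ci_high_ms == 200.0
        assert not ci.flat_curve

    def test_ci_endpoints_on_time_grid(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 500, 51)
        data = np.exp(-((t - 100) / 40) ** 2)[None] \
            + 0.2 * rng.standard_normal((10, 51))
        ci = bootstrap_peak_ci(data, t, (0, 500), n_boot=500, seed=2)
        assert ci.ci_low_ms in t and ci.ci_high_ms in t
        assert ci.ci_low_ms <= ci.estimate_ms <= ci.ci_high_ms

    def test_coverage_of_known_peak(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 400, 41)
        truth = np.exp(-((t - 100) / 60) ** 2)
        covered = 0
        n_rep = 200
        for r in range(n_rep):
            data = truth[None] + 0.1 * rng.standard_normal((8, t.size))
            ci = bootstrap_peak_ci(data, t, (0, 400), n_boot=200,
                                   seed=1000 + r)
            covered += ci.ci_low_ms <= 100.0 <= ci.ci_high_ms
        assert covered / n_rep >= 0.93

    def test_peak_difference_mode(self):
        t = np.linspace(0, 500, 51)
        a = np.tile(np.exp(-((t - 100) / 40) ** 2), (6, 1))
        b = np.tile(np.exp(-((t - 200) / 40) ** 2), (6, 1))
        ci = bootstrap_peak_ci(a, t, (0, 500), n_boot=100, seed=4,
                               mode="peak_difference", subject_data_b=b)
        assert ci.estimate_ms == -100.0

    def test_onset_mode_and_flat_flag(self):
        t = np.linspace(0, 100, 11)
        data = np.tile((t >= 50).astype(float), (5, 1))
        ci = bootstrap_peak_ci(data, t, (0, 100), n_boot=50, seed=5,
                               mode="onset", onset_criterion=0.5)
        assert ci.estimate_ms == 50.0
        with pytest.warns(UserWarning, match="flat"):
            flat = bootstrap_peak_ci(np.ones((5, 11)), t, (0, 100),
                                     n_boot=20, seed=6)
        assert flat.flat_curve
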