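"""Synthetic generator, missingness injectors and the evaluation harness."""

import math

import numpy as np
import pytest
from scipy import stats

from omicsfill import (
    EnsembleConfig,
    ImputerConfig,
    SimulationConfig,
    add_noise,
    correlation_network,
    generate_multiomics,
    inject_mar,
    inject_mcar,
    network_recovery_roc,
    paired_t_test,
    run_benchmark,
    subsample_samples,
)

from conftest import make_matrix


SMALL = SimulationConfig(n_samples=30, n_features=(50, 20, 40), seed=3)


class TestGenerateMultiomics:
    def test_deterministic(self):
        a = generate_multiomics(SMALL)
        b = generate_multiomics(SMALL)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.values, mb.values)

    def test_noiseless_matrices_have_latent_rank(self):
        cfg = SimulationConfig(n_samples=20, n_features=(30, 15),
                               omics_names=("a", "b"), latent_rank=3,
                               noise_sd=0.0, seed=1)
        for m in generate_multiomics(cfg):
            assert np.linalg.matrix_rank(m.values, tol=1e-8) <= 3

    def test_layers_share_latent_structure(self):
        # canonical correlations between any two layers reflect the shared
        # rank-3 factors
        from sklearn.cross_decomposition import CCA

        top_cors = []
        for seed in range(10):
            cfg = SimulationConfig(n_samples=50, n_features=(60, 40),
                                   omics_names=("a", "b"), latent_rank=3,
                                   noise_sd=0.3, seed=seed)
            a, b = generate_multiomics(cfg)
            cca = CCA(n_components=3, max_iter=1000)
            U, V = cca.fit_transform(a.values.T, b.values.T)
            cors = [abs(np.corrcoef(U[:, i], V[:, i])[0, 1]) for i in range(3)]
            top_cors.append(min(cors))
        assert np.mean([c > 0.8 for c in top_cors]) >= 0.9


class TestInjectMCAR:
    def test_zero_rate_noop(self, rng):
        m = make_matrix(rng.standard_normal((10, 10)))
        out, loc = inject_mcar(m, 0.0, 1)
        assert out.n_missing == 0 and len(loc) == 0

    def test_exact_count(self, rng):
        m = make_matrix(rng.standard_normal((100, 50)))
        out, loc = inject_mcar(m, 0.05, 2)
        assert out.n_missing == 250
        assert len(loc) == 250

    def test_locations_match_mask(self, rng):
        m = make_matrix(rng.standard_normal((20, 10)))
        out, loc = inject_mcar(m, 0.1, 3)
        for _, r, c in loc:
            assert out.missing_mask[r, c]
            assert math.isnan(out.values[r, c])


class TestInjectMAR:
    def test_block_structure(self, rng):
        m = make_matrix(rng.standard_normal((60, 20)))
        out, loc = inject_mar(m, 0.05, block_size=5, seed=4)
        # every masked column-run sits in a contiguous block of >= 1 rows;
        # count is near the target
        target = round(0.05 * 60 * 20)
        assert abs(out.n_missing - target) <= 5 * 20

    def test_block_size_one_is_entrywise(self, rng):
        m = make_matrix(rng.standard_normal((30, 10)))
        out, _ = inject_mar(m, 0.1, block_size=1, seed=5)
        assert out.n_missing >= round(0.1 * 300)

    def test_neighbouring_rows_share_missingness(self, rng):
        m = make_matrix(rng.standard_normal((80, 15)))
        out, _ = inject_mar(m, 0.08, block_size=4, seed=6)
        mask = out.missing_mask
        # for each masked entry, some adjacent row is masked in the same
        # column (runs of length >= 2 for interior anchors)
        rows, cols = np.nonzero(mask)
        has_neighbour = [
            (r > 0 and mask[r - 1, c]) or (r < 79 and mask[r + 1, c])
            for r, c in zip(rows, cols)]
        assert np.mean(has_neighbour) > 0.9


class TestAddNoiseAndSubsample:
    def test_zero_sd_noop(self, rng):
        m = make_matrix(rng.standard_normal((5, 5)))
        np.testing.assert_array_equal(add_noise(m, 0.0, 1).values, m.values)

    def test_noise_sd_calibrated(self, rng):
        m = make_matrix(rng.standard_normal((100, 100)))
        noisy = add_noise(m, 0.5, 7)
        diff = (noisy.values - m.values).ravel()
        assert 0.48 <= diff.std() <= 0.52

    def test_subsample_identity_and_shared_subset(self):
        oset = generate_multiomics(SMALL)
        same = subsample_samples(oset, 30, 1)
        np.testing.assert_array_equal(same[0].values, oset[0].values)
        sub = subsample_samples(oset, 10, 2)
        ids = sub[0].sample_ids
        for m in sub:
            assert m.sample_ids == ids
            assert len(ids) == 10
        # order preserved
        orig_order = [oset.sample_ids.index(s) for s in ids]
        assert orig_order == sorted(orig_order)

    def test_subsample_out_of_range(self):
        oset = generate_multiomics(SMALL)
        with pytest.raises(ValueError):
            subsample_samples(oset, 1, 0)


class TestPairedTTest:
    def test_equal_vectors_p_one(self):
        assert paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_hand_example(self):
        # differences [1,2,3]: t = 2*sqrt(3), df=2 -> p ~ 0.0742
        p = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_matches_scipy(self, rng):
        a = rng.standard_normal(15)
        b = a + 0.3 + 0.2 * rng.standard_normal(15)
        assert paired_t_test(a, b) == pytest.approx(stats.ttest_rel(a, b).pvalue)


class TestCorrelationNetwork:
    def test_self_and_anti_correlation(self, rng):
        x = rng.standard_normal(20)
        a = make_matrix(np.vstack([x, -x]))
        r = correlation_network(a, a)
        assert r[0, 0] == pytest.approx(1.0)
        assert r[0, 1] == pytest.approx(-1.0)

    def test_three_sample_hand_example(self):
        a = make_matrix(np.array([[1.0, 2.0, 3.0]]))
        b = make_matrix(np.array([[1.0, 2.0, 4.0]]))
        assert correlation_network(a, b)[0, 0] == pytest.approx(0.9820, abs=1e-4)

    def test_zero_variance_feature_zeroed(self, rng):
        a = make_matrix(np.vstack([np.ones(10), rng.standard_normal(10)]))
        b = make_matrix(rng.standard_normal((3, 10)))
        with pytest.warns(UserWarning, match="zero-variance"):
            r = correlation_network(a, b)
        assert (r[0] == 0).all()


class TestNetworkRecoveryROC:
    def test_perfect_classifier_auc_one(self, rng):
        truth = rng.uniform(-1, 1, size=(20, 30))
        _, _, auc = network_recovery_roc(truth, truth, -0.55)
        assert auc == 1.0

    def test_noise_scores_auc_near_half(self):
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            truth = r.uniform(-1, 1, size=(30, 40))
            noise = r.uniform(-1, 1, size=(30, 40))
            _, _, auc = network_recovery_roc(truth, noise, -0.55)
            aucs.append(auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_positive_threshold_direction(self, rng):
        truth = rng.uniform(-1, 1, size=(10, 10))
        _, _, auc = network_recovery_roc(truth, truth, 0.5)
        assert auc == 1.0

    def test_roc_monotone(self, rng):
        truth = rng.uniform(-1, 1, size=(20, 20))
        noisy = truth + 0.3 * rng.standard_normal((20, 20))
        fpr, tpr, auc = network_recovery_roc(truth, noisy, -0.5)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert 0.0 <= auc <= 1.0

    def test_no_positives_raises(self):
        truth = np.full((5, 5), 0.1)
        with pytest.raises(ValueError, match="ROC"):
            network_recovery_roc(truth, truth, -0.9)


class TestRunBenchmark:
    def test_single_cell_single_method(self):
        cfg = SimulationConfig(n_samples=25, n_features=(40, 20, 30),
                               n_replicates=1, seed=11)
        report = run_benchmark(cfg, ["lls"], sweep={"missing_rate": [0.05]},
                               arms=("single",),
                               imputer_kwargs={"lls": {"k_lls": 5}})
        assert len(report.nrmse_long) == 1
        assert report.nrmse_long.iloc[0]["nrmse"] > 0

    def test_paired_design_reproducible(self):
        # within a replicate every method/arm sees the same data and mask;
        # a re-run with the same seed reproduces the table bit-for-bit
        cfg = SimulationConfig(n_samples=25, n_features=(40, 20, 30),
                               n_replicates=2, seed=12)
        kw = {"lls": {"k_lls": 5}, "knn": {}}
        a = run_benchmark(cfg, ["lls", "knn"], sweep={"missing_rate": [0.05]},
                          arms=("single",), imputer_kwargs=kw)
        b = run_benchmark(cfg, ["lls", "knn"], sweep={"missing_rate": [0.05]},
                          arms=("single",), imputer_kwargs=kw)
        np.testing.assert_array_equal(a.nrmse_long["nrmse"].to_numpy(),
                                      b.nrmse_long["nrmse"].to_numpy())

    def test_report_files_written(self, tmp_path):
        cfg = SimulationConfig(n_samples=20, n_features=(30, 15, 20),
                               n_replicates=2, seed=13)
        report = run_benchmark(cfg, ["knn"], sweep={"missing_rate": [0.05]},
                               arms=("single",))
        report.to_files(tmp_path)
        assert (tmp_path / "nrmse_long.tsv").exists()
        assert (tmp_path / "report.json").exists()
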