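"""Faking-missing generation, simplex weight estimation and model combination."""

import itertools

import numpy as np
import pytest

from omicsfill import (
    EnsembleConfig,
    ImputerConfig,
    MissingLocations,
    multi_omics_impute,
    nrmse,
)
from omicsfill.ensemble import (
    BasicModelOutput,
    EnsembleWeights,
    combine,
    estimate_weights,
    generate_basic_models,
    make_faking_missing,
    solve_simplex_weights,
)

from conftest import latent_factor_pair, make_matrix


def grid_search_simplex(X, y, step=0.01):
    """Exhaustive simplex grid oracle for <= 3 models."""
    n_models = X.shape[1]
    best = np.inf
    steps = int(round(1 / step))
    if n_models == 1:
        return float(np.sum((y - X[:, 0]) ** 2))
    for combo in itertools.product(range(steps + 1), repeat=n_models - 1):
        if sum(combo) > steps:
            continue
        w = np.array(list(combo) + [steps - sum(combo)]) * step
        best = min(best, float(np.sum((y - X @ w) ** 2)))
    return best


class TestMakeFakingMissing:
    def test_zero_fraction_empty(self, rng):
        m = make_matrix(rng.standard_normal((10, 10)))
        assert len(make_faking_missing(m, 0.0, 1)) == 0

    def test_disjoint_from_true_missing(self, rng):
        vals = rng.standard_normal((20, 10))
        mask = rng.random((20, 10)) < 0.2
        mask[mask.all(axis=1)] = False
        vals[mask] = np.nan
        m = make_matrix(vals, mask)
        fakes = make_faking_missing(m, 0.1, 7)
        for _, r, c in fakes:
            assert not mask[r, c]

    def test_exact_count(self, rng):
        vals = rng.standard_normal((100, 10))
        mask = np.zeros((100, 10), bool)
        flat = rng.choice(1000, 50, replace=False)
        mask[np.unravel_index(flat, (100, 10))] = True
        vals[mask] = np.nan
        m = make_matrix(vals, mask)
        # observed = 950, fraction 0.05 -> round(47.5) = 48
        assert len(make_faking_missing(m, 0.05, 3)) == 48

    def test_reproducible_given_seed(self, rng):
        m = make_matrix(rng.standard_normal((15, 8)))
        a = make_faking_missing(m, 0.1, 11)
        b = make_faking_missing(m, 0.1, 11)
        assert a.triples == b.triples


class TestSolveSimplexWeights:
    def test_single_model_weight_one(self):
        w = solve_simplex_weights(np.ones((5, 1)), np.ones(5))
        np.testing.assert_allclose(w, [1.0])

    def test_perfect_model_gets_all_weight(self, rng):
        y = rng.standard_normal(60)
        X = np.column_stack([y, y + 1.0])
        w = solve_simplex_weights(X, y)
        assert w[0] == pytest.approx(1.0, abs=1e-6)
        assert w[1] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("n_models", [2, 3])
    def test_matches_grid_search_oracle(self, n_models, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = r.standard_normal(40)
            X = y[:, None] + 0.5 * r.standard_normal((40, n_models))
            w = solve_simplex_weights(X, y)
            assert w.min() >= -1e-12
            assert abs(w.sum() - 1) < 1e-8
            obj = float(np.sum((y - X @ w) ** 2))
            assert obj <= grid_search_simplex(X, y) + 1e-6

    def test_degenerate_identical_columns_uniform(self, rng):
        col = rng.standard_normal(20)
        X = np.column_stack([col, col, col])
        np.testing.assert_allclose(solve_simplex_weights(X, col), np.full(3, 1 / 3))


class TestEstimateWeights:
    def _models(self, preds, locs):
        return [BasicModelOutput(i, 0, f"m{i}", locs, p)
                for i, p in enumerate(preds)]

    def test_single_model(self, rng):
        locs = MissingLocations([(0, 0, j) for j in range(10)])
        w = estimate_weights(self._models([rng.standard_normal(10)], locs),
                             rng.standard_normal(10), EnsembleConfig(T=5))
        np.testing.assert_allclose(w.weights, [1.0])

    def test_truth_matching_model_dominates(self, rng):
        truth = rng.standard_normal(80)
        locs = MissingLocations([(0, 0, 0)] )  # placeholder locations
        models = self._models([truth, truth + 1.0], locs)
        w = estimate_weights(models, truth, EnsembleConfig(T=30, seed=2),
                             fake_positions=np.arange(80))
        assert w.weights[0] > 0.99

    def test_simplex_constraints_always_hold(self, rng):
        truth = rng.standard_normal(30)
        locs = MissingLocations([(0, 0, 0)])
        preds = [truth + rng.standard_normal(30) * s for s in (0.1, 0.5, 1.0, 2.0)]
        w = estimate_weights(self._models(preds, locs), truth,
                             EnsembleConfig(T=15, seed=1),
                             fake_positions=np.arange(30))
        assert w.weights.min() >= 0
        assert abs(w.weights.sum() - 1) < 1e-8


class TestCombine:
    def test_projection_on_single_weighted_model(self, rng):
        m, _, _, loc = latent_factor_pair(1, p_target=10, p_sources=(20,))
        ests = [rng.standard_normal(len(loc)) for _ in range(3)]
        models = [BasicModelOutput(i, 0, f"m{i}", loc, e)
                  for i, e in enumerate(ests)]
        w = EnsembleWeights(np.array([0.0, 1.0, 0.0]), ["a", "b", "c"])
        out = combine(models, w, m, loc)
        got = np.array([out.values[r, c] for _, r, c in loc])
        np.testing.assert_allclose(got, ests[1])

    def test_weighted_average_hand_example(self):
        vals = np.array([[1.0, np.nan], [0.0, 1.0]])
        m = make_matrix(vals)
        loc = MissingLocations([(0, 0, 1)])
        models = [BasicModelOutput(0, 0, "a", loc, np.array([2.0])),
                  BasicModelOutput(1, 0, "b", loc, np.array([6.0]))]
        w = EnsembleWeights(np.array([0.25, 0.75]), ["a", "b"])
        out = combine(models, w, m, loc)
        assert out.values[0, 1] == pytest.approx(5.0)

    def test_observed_entries_bit_identical(self, rng):
        m, _, _, loc = latent_factor_pair(2, p_target=10, p_sources=(20,))
        models = [BasicModelOutput(0, 0, "a", loc, rng.standard_normal(len(loc)))]
        out = combine(models, EnsembleWeights(np.array([1.0]), ["a"]), m, loc)
        obs = ~m.missing_mask
        assert (out.values[obs] == m.values[obs]).all()


class TestGenerateBasicModels:
    def test_cardinality_and_distinct_indices(self):
        m, _, sources, loc = latent_factor_pair(3, p_target=30, p_sources=(40, 40))
        cfg = EnsembleConfig(B=2, T=5, base=ImputerConfig(method="lls", k_lls=5))
        models = generate_basic_models(m, sources, loc, cfg)
        assert len(models) == 6
        assert len({(x.source_index, x.subsample_index) for x in models}) == 6

    def test_no_sources_single_b_is_self_imputation(self):
        m, _, _, loc = latent_factor_pair(4, p_target=30, p_sources=(10,))
        cfg = EnsembleConfig(B=1, subsample_fraction=1.0, T=5,
                             base=ImputerConfig(method="lls", k_lls=5))
        models = generate_basic_models(m, [], loc, cfg)
        assert len(models) == 1
        from omicsfill import impute

        self_out = impute(m, cfg.base)
        expected = np.array([self_out.values[r, c] for _, r, c in loc])
        np.testing.assert_allclose(models[0].estimates, expected)

    def test_full_fraction_replicates_identical(self):
        m, _, sources, loc = latent_factor_pair(5, p_target=25, p_sources=(30,))
        cfg = EnsembleConfig(B=2, subsample_fraction=1.0, T=5,
                             base=ImputerConfig(method="lls", k_lls=5))
        models = generate_basic_models(m, sources, loc, cfg)
        by_source = {}
        for x in models:
            by_source.setdefault(x.source_index, []).append(x.estimates)
        for ests in by_source.values():
            np.testing.assert_allclose(ests[0], ests[1])


class TestMultiOmicsImpute:
    def test_complete_target_returned_unchanged(self, rng):
        m = make_matrix(rng.standard_normal((10, 10)))
        res = multi_omics_impute(m, [], EnsembleConfig(T=3))
        np.testing.assert_array_equal(res.matrix.values, m.values)
        assert "no missing" in res.report["note"]

    def test_weights_on_simplex_and_convex_hull(self):
        m, truth, sources, loc = latent_factor_pair(6, p_target=40,
                                                    p_sources=(80, 60))
        cfg = EnsembleConfig(B=2, T=5, base=ImputerConfig(method="lls", k_lls=5),
                             seed=3)
        res = multi_omics_impute(m, sources, cfg)
        w = res.weights.weights
        assert w.min() >= 0 and abs(w.sum() - 1) < 1e-8
        assert np.isfinite(res.matrix.values).all()

    def test_deterministic_under_seed(self):
        m, _, sources, _ = latent_factor_pair(7, p_target=30, p_sources=(50,))
        cfg = EnsembleConfig(B=2, T=5, base=ImputerConfig(method="lls", k_lls=5),
                             seed=9)
        a = multi_omics_impute(m.copy(), [s.copy() for s in sources], cfg)
        b = multi_omics_impute(m.copy(), [s.copy() for s in sources], cfg)
        np.testing.assert_array_equal(a.matrix.values, b.matrix.values)
        np.testing.assert_array_equal(a.weights.weights, b.weights.weights)

    def test_null_sources_close_to_self_imputation(self):
        # sources carrying no signal: ensemble drifts to the self models
        ratios = []
        for seed in range(5):
            m, truth, _, loc = latent_factor_pair(seed, p_target=60,
                                                  p_sources=(30,),
                                                  missing_rate=0.08)
            r = np.random.default_rng(1000 + seed)
            from omicsfill import OmicsMatrix, impute

            noise_src = OmicsMatrix(r.standard_normal((80, 50)),
                                    np.zeros((80, 50), bool),
                                    [f"n{i}" for i in range(80)],
                                    list(m.sample_ids), "noise")
            cfg = ImputerConfig(method="lls", k_lls=8)
            res = multi_omics_impute(m, [noise_src],
                                     EnsembleConfig(B=2, T=10, base=cfg, seed=seed))
            e_multi = nrmse([truth], [res.matrix], loc)
            e_self = nrmse([truth], [impute(m, cfg)], loc)
            ratios.append(e_multi / e_self)
        assert np.mean(ratios) < 1.05
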