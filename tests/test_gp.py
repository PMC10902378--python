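import numpy as np
import pytest

from mlde.encoding import encode_variant
from mlde.gp import (
    GPHyperparameters,
    cross_validate,
    fit_gp,
    predict,
    r_squared,
    rank_candidates,
    se_kernel,
)
from mlde.synthetic import enumerate_variants, make_landscape, random_variants, true_activity

from conftest import landscape_xy, parent_seq_for


def _random_xy(n, d, seed):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, d)), rng.normal(size=n)


class TestFitAndPredict:
    def test_single_point_closed_form(self):
        hyper = GPHyperparameters(sigma_f2=2.0, length_scale=1.0, sigma_n2=0.5)
        model = fit_gp((np.array([[1.0, 2.0]]), np.array([3.0])), hyper)
        mean, var = predict(model, np.array([[1.0, 2.0]]))
        assert mean[0] == pytest.approx(3.0 * 2.0 / (2.0 + 0.5))
        assert 0 < var[0] < 2.0

    def test_noise_free_model_interpolates_training_labels(self):
        X, y = _random_xy(12, 3, seed=0)
        model = fit_gp((X, y), GPHyperparameters(1.0, 1.0, 0.0))
        mean, _ = predict(model, X)
        np.testing.assert_allclose(mean, y, atol=1e-6)

    def test_predictions_match_dense_inverse_oracle(self):
        # naive linear-algebra oracle: direct solve against (K + sigma_n^2 I)
        hyper = GPHyperparameters(sigma_f2=1.7, length_scale=0.8, sigma_n2=0.3)
        X, y = _random_xy(30, 5, seed=1)
        Xs, _ = _random_xy(8, 5, seed=2)
        model = fit_gp((X, y), hyper)
        mean, var = predict(model, Xs)

        Ky = se_kernel(X, X, hyper) + hyper.sigma_n2 * np.eye(30)
        Ks = se_kernel(X, Xs, hyper)
        mean_oracle = Ks.T @ np.linalg.solve(Ky, y)
        var_oracle = hyper.sigma_f2 - np.sum(Ks * np.linalg.solve(Ky, Ks), axis=0)
        np.testing.assert_allclose(mean, mean_oracle, atol=1e-8)
        np.testing.assert_allclose(var, var_oracle, atol=1e-8)

    def test_cholesky_state_invariants(self):
        hyper = GPHyperparameters(1.0, 1.0, 0.2)
        X, y = _random_xy(20, 4, seed=3)
        model = fit_gp((X, y), hyper)
        Ky = se_kernel(X, X, hyper) + 0.2 * np.eye(20)
        rebuilt = model.L @ model.L.T
        assert np.linalg.norm(rebuilt - Ky) / np.linalg.norm(Ky) < 1e-8
        np.testing.assert_allclose(Ky @ model.alpha, y, atol=1e-8)

    def test_matches_scikit_learn_reference(self):
        # the ecosystem reference implementation as an independent oracle
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        hyper = GPHyperparameters(1.3, 0.9, 0.2)
        X, y = _random_xy(25, 4, seed=4)
        Xs, _ = _random_xy(7, 4, seed=5)
        model = fit_gp((X, y), hyper)
        mean, var = predict(model, Xs)
        ref = GaussianProcessRegressor(
            kernel=ConstantKernel(1.3, "fixed") * RBF(0.9, "fixed"),
            alpha=0.2, optimizer=None,
        ).fit(X, y)
        mean_ref, sd_ref = ref.predict(Xs, return_std=True)
        np.testing.assert_allclose(mean, mean_ref, atol=1e-8)
        np.testing.assert_allclose(var, sd_ref**2, atol=1e-6)
        assert model.log_marginal_likelihood == pytest.approx(
            ref.log_marginal_likelihood(), abs=1e-8
        )

    def test_far_candidate_reverts_to_prior(self):
        hyper = GPHyperparameters(sigma_f2=1.5, length_scale=0.5, sigma_n2=0.1)
        X, y = _random_xy(10, 3, seed=6)
        model = fit_gp((X, y), hyper)
        mean, var = predict(model, np.full((1, 3), 100.0))
        assert abs(mean[0]) < 1e-10
        assert var[0] == pytest.approx(1.5, abs=1e-10)

    def test_duplicate_of_training_input_shrinks_variance(self):
        hyper = GPHyperparameters(sigma_f2=1.0, length_scale=1.0, sigma_n2=0.3)
        X, y = _random_xy(10, 3, seed=7)
        model = fit_gp((X, y), hyper)
        _, var = predict(model, X[:1])
        assert 0 < var[0] < 1.0

    def test_batch_equals_single_candidate_calls(self):
        hyper = GPHyperparameters(1.0, 1.0, 0.1)
        X, y = _random_xy(15, 4, seed=8)
        Xs, _ = _random_xy(100, 4, seed=9)
        model = fit_gp((X, y), hyper)
        mean_b, var_b = predict(model, Xs)
        for i in range(100):
            m1, v1 = predict(model, Xs[i : i + 1])
            assert m1[0] == pytest.approx(mean_b[i], abs=1e-12)
            assert v1[0] == pytest.approx(var_b[i], abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = fit_gp((np.zeros((3, 4)), np.zeros(3)), GPHyperparameters())
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((2, 5)))


class TestHyperparameterOptimization:
    def test_optimum_is_a_local_maximum_of_the_evidence(self, aa_table, five_site_landscape):
        _, X, y = landscape_xy(five_site_landscape, 60, seed=21, table=aa_table,
                               noise_sd=0.1)
        model = fit_gp((X, y), seed=0, restarts=3)
        h = model.hyper
        for perturbed in [
            GPHyperparameters(h.sigma_f2 * 1.1, h.length_scale, h.sigma_n2),
            GPHyperparameters(h.sigma_f2 * 0.9, h.length_scale, h.sigma_n2),
            GPHyperparameters(h.sigma_f2, h.length_scale * 1.1, h.sigma_n2),
            GPHyperparameters(h.sigma_f2, h.length_scale * 0.9, h.sigma_n2),
            GPHyperparameters(h.sigma_f2, h.length_scale, h.sigma_n2 * 1.1),
            GPHyperparameters(h.sigma_f2, h.length_scale, h.sigma_n2 * 0.9),
        ]:
            other = fit_gp((X, y), perturbed)
            assert other.log_marginal_likelihood <= model.log_marginal_likelihood + 1e-6

    def test_noise_variance_recovery_within_factor_three(self, aa_table):
        # additive descriptor-linear landscapes, label noise at a tenth of the
        # effect scale: optimized noise variance tracks the generating one
        true_var = 0.05**2
        ratios = []
        for seed in range(10):
            land = make_landscape([1, 2, 3, 4, 5], "ACDEFGHIKLMNPQRSTVWY",
                                  effect_sd=0.5, seed=seed,
                                  effect_model="descriptor_linear")
            _, X, y = landscape_xy(land, 400, seed=seed + 50, table=aa_table,
                                   noise_sd=0.05)
            model = fit_gp((X, y), seed=seed, restarts=2)
            ratios.append(model.hyper.sigma_n2 / true_var)
        assert 1 / 3 <= np.median(ratios) <= 3


class TestCrossValidation:
    def test_same_seed_gives_identical_folds_and_scores(self):
        X, y = _random_xy(40, 6, seed=10)
        a = cross_validate((X, y), k=5, seed=3, restarts=1)
        b = cross_validate((X, y), k=5, seed=3, restarts=1)
        assert a.assignments == b.assignments
        assert a.fold_r2 == b.fold_r2

    def test_folds_partition_the_rows(self):
        X, y = _random_xy(43, 3, seed=11)
        rep = cross_validate((X, y), k=10, seed=0,
                             hyperparameters=GPHyperparameters(1.0, 1.0, 0.1))
        flat = sorted(i for fold in rep.assignments for i in fold)
        assert flat == list(range(43))
        assert rep.n_folds == 10

    def test_zero_variance_fold_flagged_and_excluded(self):
        X = np.arange(20, dtype=float).reshape(-1, 1)
        y = np.ones(20)  # every fold has zero label variance
        rep = cross_validate((X, y), k=4, seed=0,
                             hyperparameters=GPHyperparameters(1.0, 1.0, 0.1))
        assert all(np.isnan(r) for r in rep.fold_r2)
        assert len(rep.flags) == 4
        assert np.isnan(rep.mean_r2)

    def test_r_squared_definition(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)


class TestRanking:
    def test_descending_by_mean_with_lexicographic_ties(self):
        hyper = GPHyperparameters(1.0, 1.0, 0.0)
        X = np.array([[0.0], [10.0]])
        y = np.array([2.0, 1.0])
        model = fit_gp((X, y), hyper)
        # candidates at the training points (means 2 and 1) plus two far-away
        # candidates that tie at the prior mean 0
        ranked = rank_candidates(
            model, (["high", "low", "z_far", "a_far"],
                    np.array([[0.0], [10.0], [99.0], [98.0]]))
        )
        assert list(ranked.index) == ["high", "low", "a_far", "z_far"]
        assert list(ranked["rank"]) == [1, 2, 3, 4]

    def test_full_three_site_space_ranking_is_a_permutation(self, aa_table):
        land = make_landscape([241, 242, 245], "ACDEFGHIKLMNPQRSTVWY",
                              effect_sd=0.5, seed=13,
                              effect_model="descriptor_linear")
        pseq = parent_seq_for(land)
        sites = list(land.sites)
        _, X, y = landscape_xy(land, 60, seed=14, table=aa_table)
        model = fit_gp((X, y), GPHyperparameters(1.0, 2.0, 0.05))
        names = []
        feats = []
        for v in enumerate_variants(land):
            names.append(v.name)
            feats.append(encode_variant(v, sites, aa_table, pseq))
        ranked = rank_candidates(model, (names, np.vstack(feats)))
        assert len(ranked) == 8000
        assert sorted(ranked["rank"]) == list(range(1, 8001))
        assert set(ranked.index) == set(names)
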