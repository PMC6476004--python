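"""Latent-variable models against independent oracles, plus validation
statistics (Q2, RPT, CV-ANOVA) on constructed signal and null data."""

import numpy as np
import pytest

from serumnmr.chemometrics import (
    correlation_loadings,
    cross_validate,
    cv_anova,
    fit_oplsda,
    fit_pca,
    fit_plsda,
    load_model,
    permutation_test,
    save_model,
    vip,
)
from serumnmr.errors import ConfigError, FitError, FoldError

SPEC_OPLS = {"kind": "oplsda", "n_orth": 1, "scaling": "uv"}


def _two_class(n):
    return np.array(["a", "b"] * (n // 2))


class TestPca:
    def test_scores_and_loadings_match_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(6, 4))
        model = fit_pca(X, n_components=4, scaling="center")
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(Xc, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for a in range(4):
            v = evecs[:, a]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(model.loadings[:, a], v, atol=1e-8)
            np.testing.assert_allclose(model.scores[:, a], Xc @ v, atol=1e-8)
        np.testing.assert_allclose(
            model.r2x_per_component, evals / evals.sum(), atol=1e-10
        )

    def test_rank_one_matrix_is_fully_explained_by_one_component(self, rng):
        X = np.outer(rng.normal(size=8), rng.normal(size=5))
        model = fit_pca(X, n_components=1, scaling="center")
        assert model.r2x == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_rows_get_identical_scores(self, rng):
        X = rng.normal(size=(5, 4))
        X2 = np.vstack([X, X])
        model = fit_pca(X2, n_components=2, scaling="center")
        np.testing.assert_allclose(model.scores[:5], model.scores[5:], atol=1e-10)

    def test_scores_are_orthogonal_and_variance_nonincreasing(self, rng):
        X = rng.normal(size=(20, 10))
        model = fit_pca(X, n_components=5)
        gram = model.scores.T @ model.scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
        assert np.all(np.diff(model.r2x_per_component) <= 1e-12)

    def test_zero_variance_matrix_is_a_fit_error(self):
        with pytest.raises(FitError):
            fit_pca(np.ones((5, 3)), n_components=1)


class TestPlsda:
    def test_constant_labels_are_a_fit_error(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(FitError):
            fit_plsda(X, np.repeat("a", 10), compute_q2=False)

    def test_first_weight_vector_is_normalized_xty(self, rng):
        X = rng.normal(size=(24, 6))
        y = _two_class(24)
        model = fit_plsda(X, y, n_components=1, scaling="uv", compute_q2=False)
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = (y == "b").astype(float)
        yc -= yc.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        # orientation may flip both weight and scores together
        sign = np.sign(w @ model.weights[:, 0])
        np.testing.assert_allclose(model.weights[:, 0], sign * w, atol=1e-10)

    def test_predictions_match_sklearn_pls_regression(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(30, 8))
        y = _two_class(30)
        model = fit_plsda(X, y, n_components=2, scaling="uv", compute_q2=False)
        sk = PLSRegression(n_components=2, scale=True).fit(X, (y == "b").astype(float))
        np.testing.assert_allclose(model.predict(X), sk.predict(X).ravel(), atol=1e-10)

    def test_strong_single_variable_signal_gives_high_q2(self, rng):
        y = _two_class(40)
        X = ((y == "b").astype(float) + rng.normal(0, 0.05, 40))[:, None]
        model = fit_plsda(X, y, n_components=1)
        assert model.q2 > 0.9

    def test_class_ordering_sets_positive_mean_score_for_second_class(self, rng):
        y = _two_class(40)
        X = rng.normal(size=(40, 5))
        X[:, 0] += 3 * (y == "b")
        model = fit_plsda(X, y, n_components=1, compute_q2=False)
        assert model.scores[y == "b", 0].mean() > 0


class TestOplsda:
    def test_without_orthogonal_components_reduces_to_pls(self, rng):
        X = rng.normal(size=(26, 9))
        y = _two_class(26)
        opls = fit_oplsda(X, y, n_orth=0, compute_q2=False)
        pls = fit_plsda(X, y, n_components=1, compute_q2=False)
        np.testing.assert_allclose(opls.scores[:, 0], pls.scores[:, 0], atol=1e-8)
        np.testing.assert_allclose(opls.weights[:, 0], pls.weights[:, 0], atol=1e-8)

    def test_orthogonal_scores_have_zero_covariance_with_response(self, rng):
        X = rng.normal(size=(30, 12))
        y = _two_class(30)
        model = fit_oplsda(X, y, n_orth=2, compute_q2=False)
        yc = model.y_encoding - model.y_encoding.mean()
        assert np.abs(model.orth_scores.T @ yc).max() < 1e-8

    def test_predictive_loading_recovers_planted_direction_despite_confounder(self, rng):
        n, p = 60, 40
        y = _two_class(n)
        yc = (y == "b").astype(float) - 0.5
        direction = rng.normal(size=p)
        direction /= np.linalg.norm(direction)
        confounder = rng.normal(size=p)
        confounder -= (confounder @ direction) * direction
        confounder /= np.linalg.norm(confounder)
        X = (
            3.0 * np.outer(yc, direction)
            + 6.0 * np.outer(rng.normal(size=n), confounder)
            + 0.1 * rng.normal(size=(n, p))
        )
        model = fit_oplsda(X, y, n_orth=1, scaling="center", compute_q2=False)
        w = model.weights[:, 0]
        cosine = abs(w @ direction) / np.linalg.norm(w)
        assert cosine > 0.95

    def test_round_trips_through_json_serialization(self, rng, tmp_path):
        X = rng.normal(size=(20, 6))
        y = _two_class(20)
        model = fit_oplsda(X, y, compute_q2=False)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_allclose(loaded.predict(X), model.predict(X), atol=1e-12)
        assert loaded.classes == model.classes


class TestCrossValidation:
    def test_perfectly_predictive_data_gives_q2_near_one(self):
        y = _two_class(28)
        X = (y == "b").astype(float)[:, None]
        q2 = cross_validate({"kind": "plsda", "n_components": 1, "scaling": "center"}, X, y)
        assert q2 > 0.999

    def test_pure_noise_q2_is_nonpositive_on_average(self, rng):
        q2s = [
            cross_validate(SPEC_OPLS, rng.normal(size=(24, 15)), _two_class(24))
            for _ in range(50)
        ]
        assert np.mean(q2s) <= 0

    def test_fixed_seed_is_reproducible(self, rng):
        X = rng.normal(size=(30, 10))
        y = _two_class(30)
        assert cross_validate(SPEC_OPLS, X, y, seed=5) == cross_validate(
            SPEC_OPLS, X, y, seed=5
        )

    def test_too_many_folds_raise(self, rng):
        X = rng.normal(size=(8, 3))
        y = _two_class(8)
        with pytest.raises(FoldError):
            cross_validate(SPEC_OPLS, X, y, k=7)


class TestPermutationTest:
    def test_observed_statistics_are_reproduced(self, rng):
        X = rng.normal(size=(24, 8))
        y = _two_class(24)
        rep = permutation_test(X, y, n_perm=20, seed=0)
        model = fit_oplsda(X, y)
        assert rep.r2y_observed == pytest.approx(model.r2y, abs=1e-12)
        assert rep.q2_observed == pytest.approx(model.q2, abs=1e-12)
        assert len(rep.permutation) == 20

    def test_strong_effect_reaches_minimal_empirical_p(self, rng):
        y = _two_class(30)
        X = rng.normal(0, 0.1, (30, 4))
        X[:, 0] += 2.0 * (y == "b")
        rep = permutation_test(X, y, n_perm=24, seed=1)
        assert rep.empirical_p == pytest.approx(1 / 25)
        # intercepts sit well below the observed statistics
        assert rep.rpt_intercepts[1] < rep.q2_observed

    def test_too_few_permutations_raise(self, rng):
        with pytest.raises(ConfigError):
            permutation_test(rng.normal(size=(10, 3)), _two_class(10), n_perm=5)


class TestCvAnova:
    def test_perfect_prediction_is_highly_significant(self):
        y = _two_class(28)
        X = (y == "b").astype(float)[:, None]
        res = cv_anova(X, y, modelspec={"kind": "plsda", "n_components": 1, "scaling": "center"})
        assert res.p < 1e-10
        assert res.F > 0 or np.isinf(res.F)

    def test_failed_cross_validation_reports_p_one(self, rng):
        X = rng.normal(size=(16, 30))
        y = _two_class(16)
        q2 = cross_validate(SPEC_OPLS, X, y, k=4)
        res = cv_anova(X, y, k=4)
        if q2 <= 0:  # PRESS >= SS: must never look significant
            assert res.p == 1.0 and res.F == 0.0
        assert res.F >= 0
        assert res.df1 == 1 and res.df2 == 16 - 1 - 2


class TestVipAndCorrelation:
    def test_identical_signal_copies_all_get_unit_vip(self, rng):
        y = _two_class(20)
        signal = (y == "b").astype(float) + rng.normal(0, 0.1, 20)
        X = np.tile(signal[:, None], (1, 5))
        model = fit_plsda(X, y, n_components=1, compute_q2=False)
        np.testing.assert_allclose(vip(model), 1.0, atol=1e-9)

    def test_mean_squared_vip_is_one(self, rng):
        X = rng.normal(size=(30, 12))
        y = _two_class(30)
        for model in (
            fit_plsda(X, y, n_components=3, compute_q2=False),
            fit_oplsda(X, y, n_orth=1, compute_q2=False),
        ):
            assert np.mean(vip(model) ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_three_variable_toy_matches_hand_formula(self, rng):
        X = rng.normal(size=(12, 3))
        y = _two_class(12)
        model = fit_plsda(X, y, n_components=1, scaling="center", compute_q2=False)
        # independent single-component derivation: w = Xc'yc normalized,
        # VIP_j = sqrt(p) |w_j| (weights are unit length)
        Xc = X - X.mean(0)
        yc = (y == "b").astype(float)
        yc -= yc.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        np.testing.assert_allclose(vip(model), np.sqrt(3) * np.abs(w), atol=1e-10)

    def test_vip_rejects_pca_models(self, rng):
        with pytest.raises(TypeError):
            vip(fit_pca(rng.normal(size=(10, 4)), 2))

    def test_correlation_loading_signs_and_bounds(self, rng):
        X = rng.normal(size=(20, 4))
        y = _two_class(20)
        X[:, 0] += 2 * (y == "b")
        model = fit_oplsda(X, y, compute_q2=False)
        t1 = model.scores[:, 0]
        probe = np.column_stack([t1, -t1, rng.normal(size=20), np.full(20, 3.0)])
        res = correlation_loadings(model, probe)
        assert res.r[0] == pytest.approx(1.0, abs=1e-10)
        assert res.r[1] == pytest.approx(-1.0, abs=1e-10)
        assert res.r[3] == 0.0 and res.undefined[3]
        assert not res.undefined[:3].any()

    def test_correlation_matches_brute_force_pearson(self, rng):
        from scipy.stats import pearsonr

        X = rng.normal(size=(10, 5))
        y = _two_class(10)
        model = fit_oplsda(X, y, compute_q2=False)
        res = correlation_loadings(model, X)
        expected = [pearsonr(X[:, j], model.scores[:, 0])[0] for j in range(5)]
        np.testing.assert_allclose(res.r, expected, atol=1e-12)
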