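"""NIPALS PLS-DA / OPLS-DA, scaling, cross-validation and permutation tests."""

import numpy as np
import pytest

from nmrfactor.multivariate import (
    correlation_loadings,
    cross_validated_q2,
    encode_labels,
    fit_oplsda,
    fit_plsda,
    nipals_pca,
    permutation_validate,
    scale_columns,
    stratified_folds,
    suggest_components,
)


def planted_two_class(n_per_class=20, p=30, effect=3.0, noise=1.0, seed=0, n_signal=5):
    """Two classes separated on a few variables, the rest pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, noise, size=(2 * n_per_class, p))
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    X[n_per_class:, :n_signal] += effect
    return X, y


class TestScaling:
    @pytest.mark.parametrize("method", ["center", "uv", "pareto"])
    def test_centering_and_roundtrip(self, method):
        rng = np.random.default_rng(1)
        X = rng.normal(3, 2, size=(15, 6))
        Xs, params = scale_columns(X, method)
        assert np.allclose(Xs.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(params.invert(Xs), X, atol=1e-10)

    def test_uv_divides_by_sd(self):
        X = np.array([[0.0], [2.0], [4.0]])  # sd = 2
        Xs, _ = scale_columns(X, "uv")
        assert np.allclose(Xs[:, 0], [-1.0, 0.0, 1.0])

    def test_pareto_divides_by_sqrt_sd(self):
        X = np.array([[0.0], [2.0], [4.0]])
        Xs, _ = scale_columns(X, "pareto")
        assert np.allclose(Xs[:, 0], np.array([-2.0, 0.0, 2.0]) / np.sqrt(2.0))

    def test_constant_column_flagged_with_unit_divisor(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        Xs, params = scale_columns(X, "uv")
        assert params.constant_columns.tolist() == [True, False]
        assert params.scales[0] == 1.0


class TestPlsda:
    def test_planted_signal_separates_and_weights_point_at_it(self):
        X, y = planted_two_class(effect=5.0, n_signal=1)
        model = fit_plsda(X, y, n_components=1)
        t = model.T[:, 0]
        a, b = t[y == "a"], t[y == "b"]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or a.max() < b.min() or b.max() < a.min()
        assert int(np.argmax(np.abs(model.W[:, 0]))) == 0

    def test_first_weight_matches_closed_form(self):
        # single-y NIPALS: w1 is normalized X_c' y_c
        X, y = planted_two_class(seed=3)
        model = fit_plsda(X, y, n_components=2)
        Xc = X - X.mean(axis=0)
        ycode = (y == "b").astype(float)
        yc = ycode - ycode.mean()
        w_expected = Xc.T @ yc
        w_expected /= np.linalg.norm(w_expected)
        assert np.abs(model.W[:, 0] @ w_expected) > 1 - 1e-8

    def test_three_class_one_hot_and_three_components(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 12))
        y = np.repeat(["ctrl", "gml", "gml_sm"], 10)
        X[10:20, 0] += 4
        X[20:, 1] += 4
        model = fit_plsda(X, y, n_components=3)
        assert model.T.shape == (30, 3)
        assert model.C.shape == (3, 3)
        assert model.classes == ["ctrl", "gml", "gml_sm"]

    def test_model_invariants(self):
        X, y = planted_two_class(seed=8)
        model = fit_plsda(X, y, n_components=3)
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()
        assert 0 <= model.r2x <= 1 and 0 <= model.r2y <= 1

    def test_component_budget_enforced(self):
        X, y = planted_two_class(n_per_class=4, p=3)
        with pytest.raises(ValueError, match="rank bound"):
            fit_plsda(X, y, n_components=5)

    def test_zero_variance_rejected(self):
        X = np.ones((8, 4))
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="zero variance"):
            fit_plsda(X, y, n_components=1)


class TestNipalsPcaOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_loadings_match_svd(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 5))
        T, P = nipals_pca(X, 3)
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        for k in range(3):
            assert abs(P[:, k] @ Vt[k]) > 1 - 1e-8


class TestCrossValidation:
    def test_folds_are_stratified_and_deterministic(self):
        y = np.array(["a"] * 16 + ["b"] * 16)
        f1 = stratified_folds(y, 8, seed=4)
        f2 = stratified_folds(y, 8, seed=4)
        assert np.array_equal(f1, f2)
        for fold in range(8):
            labels = set(y[f1 == fold])
            assert labels == {"a", "b"}

    def test_strong_separation_gives_high_q2(self):
        X, y = planted_two_class(effect=6.0, seed=10)
        report = cross_validated_q2(X, y, n_components=2, n_folds=8, seed=0)
        assert report.q2 > 0.9

    @pytest.mark.parametrize("seed", range(20))
    def test_null_data_gives_low_q2(self, seed):
        # study-scale n: labels independent of X must not look predictive
        rng = np.random.default_rng(1000 + seed)
        X = rng.normal(size=(48, 25))
        y = np.array(["a", "b"] * 24)
        report = cross_validated_q2(X, y, n_components=2, n_folds=8, seed=seed)
        assert report.q2 <= 0.1

    @pytest.mark.parametrize("seed", range(10))
    def test_q2_never_exceeds_r2y(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(24, 15))
        X[12:, :3] += rng.uniform(0, 4)
        y = np.array(["a"] * 12 + ["b"] * 12)
        report = cross_validated_q2(X, y, n_components=2, n_folds=8, seed=seed)
        assert report.q2 <= report.r2y

    def test_single_class_training_fold_rejected(self):
        X = np.random.default_rng(0).normal(size=(9, 4))
        y = np.array(["a"] * 8 + ["b"])  # the lone 'b' leaves training folds pure 'a'
        with pytest.raises(ValueError, match="fewer folds"):
            cross_validated_q2(X, y, n_components=1, n_folds=8, seed=0)


class TestPermutationValidation:
    def test_planted_effect_has_small_p(self):
        X, y = planted_two_class(effect=5.0, seed=2)
        report = permutation_validate(X, y, n_permutations=199, n_components=2, seed=0)
        assert report.p_q2 <= 0.01
        assert report.n_permutations == 199
        assert len(report.perm_q2) == 199
        assert 0 < report.p_q2 <= 1

    def test_degenerate_two_sample_design_rejected(self):
        X = np.random.default_rng(0).normal(size=(2, 4))
        y = np.array(["a", "b"])
        with pytest.raises(ValueError, match="distinct label arrangements"):
            permutation_validate(X, y, n_permutations=20, n_components=1)

    def test_too_few_permutations_rejected(self):
        X, y = planted_two_class(n_per_class=5)
        with pytest.raises(ValueError, match=">= 20"):
            permutation_validate(X, y, n_permutations=5)


class TestOplsda:
    def test_no_orthogonal_structure_leaves_nothing_to_remove(self):
        # X = y p' exactly: orthogonal variation should be ~0
        rng = np.random.default_rng(6)
        y = np.array(["a"] * 10 + ["b"] * 10)
        yc = (y == "b").astype(float) - 0.5
        p = rng.normal(size=15)
        X = np.outer(yc, p)
        model = fit_oplsda(X, y, n_orthogonal=1)
        if model.n_orthogonal:
            ortho_ss = np.sum(model.T_ortho**2)
            assert ortho_ss < 1e-10 * np.sum(model.t_pred**2)

    def test_constructed_factor_recovery(self):
        # X = y p' + t_o p_o' with t_o orthogonal to y
        rng = np.random.default_rng(9)
        n, nvar = 24, 20
        y = np.array(["a"] * 12 + ["b"] * 12)
        yc = (y == "b").astype(float)
        yc = yc - yc.mean()
        t_o = rng.normal(size=n)
        t_o -= t_o.mean()
        t_o -= (t_o @ yc) / (yc @ yc) * yc  # enforce orthogonality to class
        p_vec = rng.normal(size=nvar)
        p_o = rng.normal(size=nvar)
        X = np.outer(yc, p_vec) + np.outer(t_o, p_o)
        model = fit_oplsda(X, y, n_orthogonal=1)
        cos = abs(model.p_pred @ p_vec) / (
            np.linalg.norm(model.p_pred) * np.linalg.norm(p_vec)
        )
        assert cos > 0.999
        corr = np.corrcoef(model.t_pred, yc)[0, 1]
        assert abs(abs(corr) - 1) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_orthogonal_scores_uncorrelated_with_class(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(26, 40))
        X[13:, :6] += 1.5
        y = np.array(["a"] * 13 + ["b"] * 13)
        model = fit_oplsda(X, y, n_orthogonal=2)
        yc = (y == "b").astype(float)
        yc -= yc.mean()
        for j in range(model.n_orthogonal):
            r = np.corrcoef(model.T_ortho[:, j], yc)[0, 1]
            assert abs(r) < 1e-6

    def test_zero_orthogonal_reduces_to_first_pls_component(self):
        X, y = planted_two_class(seed=12)
        opls = fit_oplsda(X, y, n_orthogonal=0)
        pls = fit_plsda(X, y, n_components=1)
        assert np.abs(opls.w_pred @ pls.W[:, 0]) > 1 - 1e-8
        assert np.allclose(np.abs(opls.t_pred), np.abs(pls.T[:, 0]), atol=1e-8)

    def test_r2x_partition_sums_to_one(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(20, 30))
        X[10:, :4] += 2
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_oplsda(X, y, n_orthogonal=2)
        Xs, _ = scale_columns(X, "center")
        recon = np.outer(model.t_pred, model.p_pred) + model.T_ortho @ model.P_ortho.T
        r2x_resid = np.sum((Xs - recon) ** 2) / np.sum(Xs**2)
        assert model.r2x_pred + model.r2x_ortho.sum() + r2x_resid == pytest.approx(1.0, abs=1e-6)

    def test_multiclass_redirected_to_plsda(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 5))
        y = np.repeat(["a", "b", "c"], 4)
        with pytest.raises(ValueError, match="fit_plsda"):
            fit_oplsda(X, y)


class TestCorrelationLoadings:
    def test_column_equal_to_class_vector_has_r_one(self):
        y = np.array(["a"] * 6 + ["b"] * 6)
        ycode = (y == "b").astype(float)
        X = np.column_stack([ycode, np.random.default_rng(0).normal(size=12)])
        table = correlation_loadings(X, y)
        assert table.r.iloc[0] == pytest.approx(1.0)

    def test_constant_column_flagged_with_zero_r(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        X = np.column_stack([np.ones(10), (y == "b").astype(float)])
        table = correlation_loadings(X, y)
        assert table.r.iloc[0] == 0.0
        assert bool(table.degenerate.iloc[0])

    def test_noise_region_zeroed_despite_true_correlation(self):
        y = np.array(["a"] * 8 + ["b"] * 8)
        ycode = (y == "b").astype(float)
        rng = np.random.default_rng(4)
        X = np.column_stack([ycode + 0.1 * rng.normal(size=16), rng.normal(size=16)])
        centers = np.array([1.0, 2.0])
        table = correlation_loadings(X, y, noise_regions=[(0.9, 1.1)], bin_centers=centers)
        assert table.r.iloc[0] == 0.0
        assert bool(table.zeroed.iloc[0])
        assert table.covariance.iloc[0] == 0.0
        assert not bool(table.zeroed.iloc[1])


class TestHelpers:
    def test_binary_coding_and_one_hot(self):
        Y, classes = encode_labels(np.array(["b", "a", "b"]))
        assert classes == ["a", "b"]
        assert Y[:, 0].tolist() == [1.0, 0.0, 1.0]
        Y3, classes3 = encode_labels(np.array(["a", "b", "c"]))
        assert Y3.shape == (3, 3) and np.allclose(Y3.sum(axis=1), 1)

    def test_suggest_components_stops_on_plateau(self):
        X, y = planted_two_class(effect=6.0, n_signal=1, seed=30)
        k = suggest_components(X, y, max_components=4, seed=0)
        assert k == 1  # one informative direction only
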