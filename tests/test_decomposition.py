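"""PCA and NIPALS PLS against independent oracles and their invariants."""

import numpy as np
import pytest

import ftirchem as fc
from ftirchem.errors import ConfigError, DegenerateDataError


def _svd_oracle(X, k):
    """Independent PCA reference via singular value decomposition."""
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:k].T
    scores = Xc @ loadings
    var = s[:k] ** 2 / (X.shape[0] - 1)
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores, var


class TestPCA:
    def test_collinear_points_have_unit_first_component(self):
        t = np.linspace(-1, 1, 12)
        X = np.column_stack([2 * t + 1, -3 * t + 0.5])
        model = fc.fit_pca(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(10, 20))
        model = fc.fit_pca(X, 5)
        L, S, var = _svd_oracle(X, 5)
        np.testing.assert_allclose(model.loadings, L, atol=1e-8)
        np.testing.assert_allclose(model.scores, S, atol=1e-8)
        np.testing.assert_allclose(model.explained_variance, var, atol=1e-8)

    def test_matches_svd_oracle_wide_and_tall(self):
        rng = np.random.default_rng(1)
        for shape in [(30, 8), (8, 30)]:
            X = rng.normal(size=shape)
            k = min(shape[0] - 1, shape[1], 4)
            model = fc.fit_pca(X, k)
            L, S, _ = _svd_oracle(X, k)
            np.testing.assert_allclose(model.loadings, L, atol=1e-8)
            np.testing.assert_allclose(model.scores, S, atol=1e-8)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 5))
        model = fc.fit_pca(X, 5)
        np.testing.assert_allclose(model.reconstruct(model.scores), X, atol=1e-8)

    def test_orthonormal_loadings_and_centered_scores(self):
        rng = np.random.default_rng(3)
        model = fc.fit_pca(rng.normal(size=(15, 40)), 6)
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(6),
                                   atol=1e-8)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0, atol=1e-10)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        assert model.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateDataError):
            fc.fit_pca(np.full((6, 4), 2.0), 2)


class TestPLS:
    def test_single_informative_column(self):
        # predictors orthogonal after centering: one latent variable then
        # captures a response proportional to a single column exactly
        rng = np.random.default_rng(0)
        B = rng.normal(size=(20, 6))
        X, _ = np.linalg.qr(B - B.mean(axis=0))
        y = 3.0 * X[:, 2]
        model = fc.fit_pls_nipals(X, y, n_lv=1)
        yhat = fc.predict_pls(model, X)
        ss_res = np.sum((yhat - y) ** 2)
        assert ss_res / np.sum((y - y.mean()) ** 2) < 1e-8

    def test_full_rank_equals_ols_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        model = fc.fit_pls_nipals(X, y, n_lv=8)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        yhat_ols = y.mean() + Xc @ beta
        np.testing.assert_allclose(fc.predict_pls(model, X), yhat_ols, atol=1e-8)

    def test_uninformative_block_gets_null_coefficients(self):
        rng = np.random.default_rng(9)
        n = 40
        block1 = rng.normal(size=(n, 5))
        block1 -= block1.mean(axis=0)  # pre-center so fit centering is a no-op
        block2 = rng.normal(size=(n, 5))
        block2 -= block2.mean(axis=0)
        y = block1 @ np.array([1.0, -2.0, 0.5, 0.0, 1.5])
        # orthogonalize block2 against block1 and y
        A = np.column_stack([block1, y])
        block2 -= A @ np.linalg.lstsq(A, block2, rcond=None)[0]
        X = np.column_stack([block1, block2])
        model = fc.fit_pls_nipals(X, y, n_lv=5)
        b = model.coef
        assert np.max(np.abs(b[5:])) < 1e-6 * np.max(np.abs(b))

    def test_dual_path_predictions_agree(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        model = fc.fit_pls_nipals(X, y, n_lv=5)
        Xn = rng.normal(size=(7, 12))
        np.testing.assert_allclose(
            model.predict(Xn), model.predict_via_scores(Xn), atol=1e-10
        )

    def test_training_rows_reproduce_fitted_values(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(18, 9))
        y = rng.normal(size=18)
        model = fc.fit_pls_nipals(X, y, n_lv=4)
        fitted = model.y_mean + model.scores @ model.y_loadings
        np.testing.assert_allclose(fc.predict_pls(model, X), fitted, atol=1e-10)

    def test_mean_row_predicts_y_mean(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(14, 6))
        y = rng.normal(size=14)
        model = fc.fit_pls_nipals(X, y, n_lv=3)
        pred = fc.predict_pls(model, X.mean(axis=0, keepdims=True))
        assert pred[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(13)
        model = fc.fit_pls_nipals(rng.normal(size=(30, 20)), rng.normal(size=30),
                                  n_lv=6)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_one_lv_is_covariance_direction(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        model = fc.fit_pls_nipals(X, y, n_lv=1)
        Xc = X - X.mean(axis=0)
        w = Xc.T @ (y - y.mean())
        w /= np.linalg.norm(w)
        np.testing.assert_allclose(np.abs(model.weights[:, 0]), np.abs(w), atol=1e-10)

    def test_training_rss_monotone_in_lv(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        rss = []
        for a in range(1, 9):
            model = fc.fit_pls_nipals(X, y, n_lv=a)
            rss.append(np.sum((fc.predict_pls(model, X) - y) ** 2))
        assert all(b <= a + 1e-10 for a, b in zip(rss, rss[1:]))

    def test_matches_independent_kernel_pls(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(16)
        X = rng.normal(size=(30, 15))
        y = X @ rng.normal(size=15) + 0.1 * rng.normal(size=30)
        model = fc.fit_pls_nipals(X, y, n_lv=5)
        ref = sklearn.PLSRegression(n_components=5, scale=False).fit(X, y)
        np.testing.assert_allclose(model.coef, ref.coef_.ravel(), atol=1e-8)

    def test_zero_variance_response_rejected(self):
        with pytest.raises(DegenerateDataError):
            fc.fit_pls_nipals(np.random.default_rng(0).normal(size=(10, 4)),
                              np.ones(10), n_lv=2)

    def test_n_lv_bounds(self):
        rng = np.random.default_rng(17)
        with pytest.raises(ConfigError):
            fc.fit_pls_nipals(rng.normal(size=(5, 3)), rng.normal(size=5), n_lv=5)
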