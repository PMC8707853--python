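import json

import numpy as np
import pytest

import nircalib as nc
from nircalib.errors import DataError
from nircalib.mpls import MPLSModel, fit_mpls, pca_describe, predict

from oracles import nipals_pls1

RNG = np.random.default_rng(7)


class TestFit:
    def test_single_channel_signal_needs_one_factor(self):
        X = np.zeros((20, 10))
        X[:, 3] = RNG.normal(size=20)
        y = 2.0 * X[:, 3]
        m = fit_mpls(X, y, 1, standardize_residuals=False)
        resid = y - predict(m, X, 1)
        assert np.sum(resid ** 2) < 1e-16

    def test_plain_pls1_matches_nipals_oracle(self):
        for _ in range(5):
            X = RNG.normal(size=(20, 30))
            y = RNG.normal(size=20)
            Xn = RNG.normal(size=(6, 30))
            m = fit_mpls(X, y, 5, standardize_residuals=False)
            oracle = nipals_pls1(X, y, 5)
            np.testing.assert_allclose(predict(m, Xn, 5), oracle(Xn), atol=1e-8)

    def test_plain_pls1_matches_sklearn(self):
        """Independent library route agrees with the hand-rolled engine."""
        from sklearn.cross_decomposition import PLSRegression
        X = RNG.normal(size=(30, 40))
        y = RNG.normal(size=30)
        Xn = RNG.normal(size=(6, 40))
        m = fit_mpls(X, y, 5, standardize_residuals=False)
        sk = PLSRegression(n_components=5, scale=False).fit(X, y)
        np.testing.assert_allclose(predict(m, Xn, 5), sk.predict(Xn).ravel(), atol=1e-8)

    def test_residual_columns_standardized_each_factor(self):
        X = RNG.normal(size=(25, 15))
        y = RNG.normal(size=25)
        m = fit_mpls(X, y, 4, standardize_residuals=True)
        Xw = X - m.x_center
        for k in range(4):
            t = Xw @ m.weights[k]
            Xw = Xw - np.outer(t, m.loadings[k])
            Xw = Xw / m.scalings[k]
            sd = Xw.std(axis=0, ddof=1)
            np.testing.assert_allclose(sd, 1.0, atol=1e-10)

    def test_rank_deficient_stops_early(self):
        X = np.outer(RNG.normal(size=20), RNG.normal(size=10))  # rank 1
        y = X[:, 0] + 0.0
        m = fit_mpls(X, y, 4, standardize_residuals=False)
        assert m.rank_deficient
        assert m.n_factors_available < 4

    def test_training_rss_nonincreasing_in_factor_count(self):
        X = RNG.normal(size=(30, 20))
        y = RNG.normal(size=30)
        m = fit_mpls(X, y, 8, standardize_residuals=True)
        rss = [np.sum((y - m.fitted_values[:, k]) ** 2)
               for k in range(m.n_factors_available + 1)]
        assert all(b <= a + 1e-10 for a, b in zip(rss, rss[1:]))

    def test_plain_pls_scores_mutually_orthogonal(self):
        """Without residual scaling, successive score vectors are orthogonal."""
        X = RNG.normal(size=(30, 20))
        y = RNG.normal(size=30)
        m0 = fit_mpls(X, y, 6, standardize_residuals=False)
        Xw = X - m0.x_center
        plain_scores = []
        for k in range(m0.n_factors_available):
            t = Xw @ m0.weights[k]
            plain_scores.append(t)
            Xw = Xw - np.outer(t, m0.loadings[k])
        T = np.column_stack(plain_scores)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_successive_score_orthogonal_to_deflated_matrix(self):
        """With scaling on, each score is orthogonal to its own deflated space."""
        X = RNG.normal(size=(30, 20))
        y = RNG.normal(size=30)
        m = fit_mpls(X, y, 6, standardize_residuals=True)
        Xw = X - m.x_center
        for k in range(m.n_factors_available):
            t = Xw @ m.weights[k]
            Xw = Xw - np.outer(t, m.loadings[k])
            # deflation removes the score direction: residual columns ⟂ t
            proj = np.abs(t @ Xw) / (np.linalg.norm(t) * np.linalg.norm(Xw, axis=0))
            assert proj.max() < 1e-8
            Xw = Xw / m.scalings[k]

    def test_full_rank_pls_equals_ols(self):
        """At n_factors = rank(X), plain PLS1 reproduces least squares."""
        X = RNG.normal(size=(15, 4))
        y = RNG.normal(size=15)
        m = fit_mpls(X, y, 4, standardize_residuals=False)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        ols_fit = y.mean() + Xc @ beta
        np.testing.assert_allclose(predict(m, X, 4), ols_fit, atol=1e-8)

    def test_duplicated_rows_do_not_change_predictions(self):
        X = RNG.normal(size=(12, 8))
        y = RNG.normal(size=12)
        Xn = RNG.normal(size=(5, 8))
        m1 = fit_mpls(X, y, 3, standardize_residuals=True)
        m2 = fit_mpls(np.vstack([X, X]), np.concatenate([y, y]), 3,
                      standardize_residuals=True)
        np.testing.assert_allclose(predict(m1, Xn, 3), predict(m2, Xn, 3), atol=1e-8)


class TestPredict:
    def test_zero_factors_predicts_calibration_mean(self):
        X = RNG.normal(size=(20, 10))
        y = RNG.normal(size=20)
        m = fit_mpls(X, y, 3)
        np.testing.assert_allclose(predict(m, RNG.normal(size=(7, 10)), 0), y.mean())

    def test_training_set_reproduces_stored_fitted_values(self):
        X = RNG.normal(size=(20, 10))
        y = RNG.normal(size=20)
        m = fit_mpls(X, y, 4, standardize_residuals=True)
        for k in range(m.n_factors_available + 1):
            np.testing.assert_allclose(predict(m, X, k), m.fitted_values[:, k], atol=1e-10)

    def test_channel_mismatch_rejected(self):
        m = fit_mpls(RNG.normal(size=(20, 10)), RNG.normal(size=20), 2)
        with pytest.raises(DataError, match="channel"):
            predict(m, RNG.normal(size=(3, 9)))

    def test_json_round_trip_lossless(self):
        X = RNG.normal(size=(20, 10))
        y = RNG.normal(size=20)
        m = fit_mpls(X, y, 3, standardize_residuals=True)
        m.n_factors_selected = 2
        back = MPLSModel.from_dict(json.loads(json.dumps(m.to_dict())))
        Xn = RNG.normal(size=(6, 10))
        np.testing.assert_array_equal(predict(back, Xn), predict(m, Xn, 2))


class TestPCA:
    def test_rank_one_single_component(self):
        X = np.outer(RNG.normal(size=20), RNG.normal(size=10))
        r = pca_describe(X, 0.996)
        assert r.n_components == 1
        assert r.explained[0] == pytest.approx(1.0)

    def test_explained_matches_covariance_eigenvalues(self):
        X = RNG.normal(size=(30, 12))
        r = pca_describe(X)
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        np.testing.assert_allclose(r.explained, eig[:len(r.explained)] / eig.sum(), atol=1e-10)

    def test_component_count_at_target(self):
        # construct data with known variance split: 99% + 0.8% + rest
        rng = np.random.default_rng(1)
        basis = np.linalg.qr(rng.normal(size=(12, 3)))[0]
        scores = rng.normal(size=(500, 3)) * np.array([np.sqrt(99.0), np.sqrt(0.8), np.sqrt(0.2)])
        X = scores @ basis.T
        r = pca_describe(X, 0.996)
        assert r.n_components == 2
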