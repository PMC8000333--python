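import warnings

import numpy as np
import pytest

from chromaqc.multivariate import (
    bootstrap_eigenvalues,
    fit_with_loo,
    loo_cv,
    pca,
    pls_predict,
    select_n_components,
    simpls_fit,
)


class TestSimpls:
    def test_univariate_collapse_equals_ols(self, rng):
        x = rng.normal(size=(8, 1))
        y = 2.0 + 3.0 * x[:, 0] + rng.normal(size=8) * 0.1
        m = simpls_fit(x, y, 1)
        coef = np.polyfit(x[:, 0], y, 1)
        np.testing.assert_allclose(m.predict(x, 1), np.polyval(coef, x[:, 0]), atol=1e-10)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(12, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=12) * 0.2
        m = simpls_fit(X, y, 5)
        Xd = np.column_stack([np.ones(12), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        assert np.max(np.abs(m.predict(X, 5) - Xd @ beta)) < 1e-8

    def test_rank1_exact_fit_one_component(self, rng):
        v = rng.normal(size=6)
        t = rng.normal(size=9)
        X = np.outer(t, v)
        y = 5.0 + 2.0 * t
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = simpls_fit(X, y, 1)
        assert m.r2_fitted[0] == pytest.approx(1.0)

    def test_scores_orthonormal(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        m = simpls_fit(X, y, 4)
        np.testing.assert_allclose(m.scores.T @ m.scores, np.eye(4), atol=1e-8)

    def test_adding_components_never_increases_ssr(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        m = simpls_fit(X, y, 5)
        ssrs = []
        for a in range(1, 6):
            resid = y - m.predict(X, a)
            ssrs.append(float(resid @ resid))
        assert all(b <= a + 1e-12 for a, b in zip(ssrs[:-1], ssrs[1:]))

    def test_excess_components_truncated_with_warning(self, rng):
        X = rng.normal(size=(5, 10))
        y = rng.normal(size=5)
        with pytest.warns(UserWarning, match="truncat"):
            m = simpls_fit(X, y, 9)
        assert m.n_components == 4

    def test_matches_sklearn_nipals_single_y(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(10, 4))
        y = X @ [1.0, -2.0, 0.5, 3.0] + rng.normal(size=10) * 0.1
        m = simpls_fit(X, y, 2)
        sk = PLSRegression(n_components=2, scale=False).fit(X, y)
        np.testing.assert_allclose(m.predict(X, 2), sk.predict(X).ravel(), atol=1e-10)


class TestLooCv:
    def test_brute_force_oracle(self, rng):
        X = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        table = loo_cv(X, y, 3)
        press = np.zeros(3)
        for i in range(9):
            mask = np.arange(9) != i
            sub = simpls_fit(X[mask], y[mask], 3)
            for a in (1, 2, 3):
                press[a - 1] += (sub.predict(X[i], a)[0] - y[i]) ** 2
        np.testing.assert_allclose(table["MSEP"].to_numpy(), press / 9, atol=1e-10)

    def test_rmsep_is_sqrt_msep(self, rng):
        X = rng.normal(size=(7, 3))
        y = rng.normal(size=7)
        table = loo_cv(X, y, 2)
        np.testing.assert_allclose(table["RMSEP"] ** 2, table["MSEP"])

    def test_noiseless_linear_rmsep_near_zero(self, rng):
        X = rng.normal(size=(10, 3))
        y = X @ [1.0, 2.0, -1.0]
        table = loo_cv(X, y, 3)
        assert table["RMSEP"].iloc[-1] < 1e-8

    def test_component_selection_prefers_small_models(self):
        import pandas as pd

        cv = pd.DataFrame({"RMSEP": [10.0, 1.02, 1.0]}, index=[1, 2, 3])
        cv.index.name = "n_components"
        assert select_n_components(cv) == 2


class TestPlsPredict:
    def test_training_row_of_noiseless_model(self, rng):
        X = rng.normal(size=(8, 3)) + 5.0
        y = 100.0 + X @ [1.0, 2.0, 3.0]
        m = fit_with_loo(X, y, max_components=3, n_components=3)
        out = pls_predict(m, X[2], nominal=None)
        assert out["estimate"].iloc[0] == pytest.approx(y[2], rel=1e-8)

    def test_jackknife_zero_width_for_stable_folds(self, rng):
        X = rng.normal(size=(8, 2))
        y = X @ [2.0, -1.0] + 4.0  # exact linear: every fold identical model
        m = fit_with_loo(X, y, max_components=2, n_components=2)
        out = pls_predict(m, X[0], nominal=None)
        assert out["upper"].iloc[0] - out["lower"].iloc[0] < 1e-8

    def test_pct_error_vs_nominal(self, rng):
        X = rng.normal(size=(8, 2)) + 3.0
        y = 100.0 + X @ [5.0, 1.0]
        m = fit_with_loo(X, y, max_components=2, n_components=2)
        out = pls_predict(m, X, nominal=160.0)
        np.testing.assert_allclose(
            out["pct_error"], 100.0 * (out["estimate"] - 160.0) / 160.0
        )

    def test_missing_columns_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        m = fit_with_loo(X, y, max_components=2)
        with pytest.raises(ValueError, match="column"):
            pls_predict(m, np.zeros((1, 2)))


class TestPca:
    def test_line_in_2d_pc1_100pct(self):
        t = np.linspace(-1, 1, 9)
        X = np.column_stack([t, 2 * t])
        r = pca(X)
        assert r.explained_pct[0] == pytest.approx(100.0)

    def test_reconstruction_identity(self, rng):
        X = rng.normal(size=(6, 23))
        r = pca(X)
        np.testing.assert_allclose(r.scores @ r.loadings.T, X - X.mean(0), atol=1e-8)

    def test_explained_sums_to_100(self, rng):
        X = rng.normal(size=(8, 5))
        assert pca(X).explained_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(10, 4))
        r = pca(X)
        cov = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(r.eigenvalues, eig, atol=1e-10)

    def test_zero_variance_with_scaling_rejected(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="zero-variance"):
            pca(X, scale=True)

    def test_eigenvalues_non_increasing(self, rng):
        r = pca(rng.normal(size=(12, 6)))
        assert np.all(np.diff(r.eigenvalues) <= 1e-12)


class TestBootstrapEigenvalues:
    def test_collinear_rows_always_100pct(self, rng):
        t = rng.normal(size=8)
        X = np.outer(t, [1.0, 2.0, 3.0])
        boot = bootstrap_eigenvalues(X, n_boot=7, seed=1)
        assert boot["mean_explained_pct"].iloc[0] == pytest.approx(100.0)

    def test_same_seed_same_output(self, rng):
        X = rng.normal(size=(9, 4))
        b1 = bootstrap_eigenvalues(X, n_boot=7, seed=42)
        b2 = bootstrap_eigenvalues(X, n_boot=7, seed=42)
        np.testing.assert_array_equal(b1.to_numpy(), b2.to_numpy())

    def test_mean_near_plugin_on_separated_data(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=40) * 5
        X = np.outer(t, [1.0, 0.5, 0.2]) + rng.normal(size=(40, 3)) * 0.3
        plug = pca(X).explained_pct[0]
        boot = bootstrap_eigenvalues(X, n_boot=200, seed=9)
        assert abs(boot["mean_explained_pct"].iloc[0] - plug) < 5.0
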