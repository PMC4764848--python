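"""PLS1 core: fit, latent selection, VIP, filtering, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridmet import PLS1, filter_and_refit, fit_pls, select_latent_number


def ols_fitted(X, y):
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ coef


class TestFit:
    def test_single_predictor_equals_simple_regression(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 2.0 + 1.5 * x + rng.normal(scale=0.3, size=30)
        res = fit_pls(x[:, None], y, k=1)
        lin = stats.linregress(x, y)
        np.testing.assert_allclose(res.params.to_numpy(), [lin.slope], rtol=1e-10)
        assert res.intercept == pytest.approx(lin.intercept)
        assert res.rsquared == pytest.approx(lin.rvalue**2)

    @pytest.mark.parametrize("p", [2, 5, 12])
    def test_full_factor_fit_matches_ols(self, p):
        rng = np.random.default_rng(p)
        X = rng.standard_normal((40, p))
        y = X @ rng.normal(size=p) + rng.normal(scale=0.5, size=40)
        res = fit_pls(X, y, k=p)
        np.testing.assert_allclose(res.fittedvalues.to_numpy(), ols_fitted(X, y),
                                   atol=1e-8)

    def test_orthogonal_response_gives_no_signal(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 3))
        y = rng.standard_normal(50)
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]  # strip projection
        y = y - y.mean()
        res = fit_pls(X - X.mean(0), y, k=1)
        assert abs(res.rsquared) < 0.05
        assert np.abs(res.params.to_numpy()).max() < 0.1

    def test_score_orthogonality(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 10))
        y = X @ rng.normal(size=10) + rng.normal(scale=1.0, size=40)
        res = fit_pls(X, y, k=8)
        assert res.score_orthogonality() < 1e-8

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant response"):
            PLS1(np.ones(10), np.random.default_rng(0).normal(size=(10, 3)))

    def test_r2_non_decreasing_in_k(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=30)
        _, table = select_latent_number(X, y)
        assert (np.diff(table["r2"].to_numpy()) >= -1e-12).all()


class TestLatentSelection:
    def test_two_latent_directions_noiseless(self):
        """Response built from exactly two orthogonal factors -> k* = 2."""
        rng = np.random.default_rng(4)
        n, p = 60, 10
        T = np.linalg.qr(rng.standard_normal((n, 2)))[0]
        P = rng.standard_normal((2, p))
        X = T @ P  # exactly rank 2: extraction ends after two factors
        y = T @ np.array([3.0, -2.0])
        res, table = select_latent_number(X, y)
        assert res.n_factors == 2
        # brute force: adjusted R2 must peak at k=2
        assert int(table.loc[table["adj_r2"].idxmax(), "k"]) == 2

    def test_pure_noise_selects_small_model(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 10))
        y = rng.standard_normal(80)
        res, _ = select_latent_number(X, y)
        assert res.n_factors <= 3
        assert res.rsquared_adj < 0.2

    def test_perfect_fit_small_n(self):
        x = np.arange(10, dtype=float)
        y = 3.0 * x + 1.0
        res, table = select_latent_number(x[:, None], y)
        assert res.n_factors == 1
        assert table.iloc[0]["adj_r2"] == pytest.approx(1.0)


class TestVIP:
    def test_equal_weights_give_unit_vip(self):
        # two identical predictors, so Factor-1 weights are equal
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        X = np.column_stack([x, x + 1e-12 * rng.standard_normal(40)])
        y = x + rng.normal(scale=0.1, size=40)
        res = fit_pls(X, y, k=1)
        np.testing.assert_allclose(res.vip.to_numpy(), [1.0, 1.0], atol=1e-5)

    def test_formula_on_known_weights(self):
        """w1 = (3, 4) -> VIP = sqrt(2)*(3, 4)/5."""
        res = fit_pls(np.eye(2), np.zeros(2) + [1, 2], k=1)  # placeholder fit
        res.x_weights = np.array([[3.0], [4.0]]) / 5.0
        np.testing.assert_allclose(
            res.vip.to_numpy(), [np.sqrt(2) * 0.6, np.sqrt(2) * 0.8], rtol=1e-12)

    def test_mean_square_vip_is_one(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((30, 12))
            y = X @ rng.normal(size=12) + rng.normal(size=30)
            res = fit_pls(X, y, k=3)
            assert np.mean(res.vip.to_numpy() ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_concentrated_weight(self):
        rng = np.random.default_rng(8)
        n, p = 50, 6
        X = rng.standard_normal((n, p))
        y = X[:, 2] * 5.0  # single causal predictor, no noise
        res = fit_pls(X, y, k=1)
        assert res.vip.idxmax() == "x2"


class TestFilterAndPredict:
    def test_filter_keeps_causal_in_sparse_signal(self):
        rng = np.random.default_rng(9)
        n, p = 120, 100
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        causal = rng.choice(p, size=10, replace=False)
        beta[causal] = rng.uniform(1, 2, 10) * rng.choice([-1, 1], 10)
        y = X @ beta + rng.normal(scale=1.0, size=n)
        refit, kept = filter_and_refit(
            pd.DataFrame(X, columns=[f"v{j}" for j in range(p)]), y, threshold=1.0)
        causal_names = {f"v{j}" for j in causal}
        assert len(causal_names & set(refit.model.var_names)) >= 9
        assert kept == refit.model.p

    def test_threshold_above_max_vip_errors(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((30, 5))
        y = X @ rng.normal(size=5)
        res = fit_pls(X, y, k=2)
        with pytest.raises(ValueError, match="lower the threshold"):
            res.filter_vip(threshold=res.vip.max() * 1.01)

    def test_retained_count_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((40, 20))
        y = X @ rng.normal(size=20) + rng.normal(size=40)
        res = fit_pls(X, y, k=5)
        counts = []
        for thr in (0.5, 0.8, 1.0, 1.2):
            try:
                counts.append(res.filter_vip(threshold=thr).model.p)
            except ValueError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)

    def test_in_sample_prediction_identity(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        y = X.to_numpy() @ rng.normal(size=4) + rng.normal(size=30)
        res = PLS1(y, X).fit(n_factors=3)
        np.testing.assert_allclose(res.predict(X).to_numpy(),
                                   res.fittedvalues.to_numpy(), rtol=1e-12)

    def test_centered_zero_features_predict_intercept(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((30, 4))
        y = X @ rng.normal(size=4) + 5.0
        res = fit_pls(X, y, k=2)
        pred = res.predict(np.zeros((1, 4)))
        assert pred.iloc[0] == pytest.approx(res.intercept)

    def test_missing_prediction_column_raises(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(size=20)
        res = PLS1(y, X).fit(n_factors=1)
        with pytest.raises(KeyError, match="c"):
            res.predict(X[["a", "b"]])


class TestCrossChecks:
    def test_against_sklearn_pls(self):
        """Independent NIPALS implementation agrees on fitted values."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(15)
        X = rng.standard_normal((50, 8))
        y = X @ rng.normal(size=8) + rng.normal(scale=0.5, size=50)
        for k in (1, 3, 5):
            mine = fit_pls(X, y, k=k)
            ref = PLSRegression(n_components=k, scale=True).fit(X, y)
            np.testing.assert_allclose(
                mine.fittedvalues.to_numpy(), ref.predict(X).ravel(), atol=1e-8)

    def test_loo_q2_reasonable_on_strong_signal(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((25, 3))
        y = X @ np.array([2.0, -1.0, 0.5]) + rng.normal(scale=0.2, size=25)
        res = fit_pls(X, y, k=3)
        assert res.loo_q2() > 0.8
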