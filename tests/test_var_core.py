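"""VAR likelihood, stability, covariance assembly and forecasting."""

import numpy as np
import pytest
from scipy import stats as sps

from pdpmvar import (
    FactorCovariance,
    PanelTimeSeries,
    VARCoefficients,
    assemble_sigma,
    forecast,
    is_stable,
    log_likelihood_subject,
)
from pdpmvar.panel import build_design


def brute_force_loglik(X, A_list, sigma):
    """Independent oracle: evaluate the product-of-conditionals density
    term by term with scipy's multivariate normal."""
    D, T = X.shape
    K = len(A_list)
    total = 0.0
    for t in range(T):
        mean = np.zeros(D)
        for k in range(1, min(t, K) + 1):
            mean += A_list[k - 1] @ X[:, t - k]
        total += sps.multivariate_normal.logpdf(X[:, t], mean=mean, cov=sigma)
    return total


class TestLogLikelihood:
    def test_all_zero_data_identity_sigma(self):
        theta = VARCoefficients(np.zeros((1, 2, 2)))
        ll = log_likelihood_subject(np.zeros((2, 5)), theta, np.eye(2))
        assert ll == pytest.approx(-5.0 * np.log(2 * np.pi))

    def test_univariate_ar1_matches_scalar_normals(self):
        # oracle: three standard-normal log-densities at (1, 0, 0)
        theta = VARCoefficients(np.array([[[0.5]]]))
        x = np.array([[1.0, 0.5, 0.25]])
        expected = sum(sps.norm.logpdf(v) for v in (1.0, 0.0, 0.0))
        assert log_likelihood_subject(x, theta, np.eye(1)) == pytest.approx(expected)

    def test_var2_truncated_lag_decomposition(self):
        # at T=3 the likelihood factors as phi(x3-A1x2-A2x1) phi(x2-A1x1) phi(x1)
        rng = np.random.default_rng(0)
        A = 0.2 * rng.standard_normal((2, 2, 2))
        sigma = np.eye(2) * 0.7
        X = rng.standard_normal((2, 3))
        theta = VARCoefficients(A)
        terms = (
            sps.multivariate_normal.logpdf(
                X[:, 2], mean=A[0] @ X[:, 1] + A[1] @ X[:, 0], cov=sigma
            )
            + sps.multivariate_normal.logpdf(X[:, 1], mean=A[0] @ X[:, 0], cov=sigma)
            + sps.multivariate_normal.logpdf(X[:, 0], mean=np.zeros(2), cov=sigma)
        )
        assert log_likelihood_subject(X, theta, sigma) == pytest.approx(terms)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force_on_random_stable_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        D = int(rng.integers(1, 4))
        K = int(rng.integers(1, 3))
        T = int(rng.integers(2, 9))
        A = 0.3 * rng.standard_normal((K, D, D)) / np.sqrt(D * K)
        theta = VARCoefficients(A)
        assert is_stable(theta)[0]
        W = rng.standard_normal((D, D + 1))
        sigma = W @ W.T / (D + 1) + 0.5 * np.eye(D)
        X = rng.standard_normal((D, T))
        assert log_likelihood_subject(X, theta, sigma) == pytest.approx(
            brute_force_loglik(X, list(A), sigma), abs=1e-8
        )

    def test_total_panel_loglik_invariant_to_subject_order(self, rng):
        theta = VARCoefficients(0.2 * rng.standard_normal((1, 3, 3)))
        sigma = np.eye(3)
        Xs = [rng.standard_normal((3, 20)) for _ in range(4)]
        fwd = sum(log_likelihood_subject(X, theta, sigma) for X in Xs)
        rev = sum(log_likelihood_subject(X, theta, sigma) for X in reversed(Xs))
        assert fwd == pytest.approx(rev)

    def test_rejects_non_spd_sigma_and_dim_mismatch(self):
        theta = VARCoefficients(np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            log_likelihood_subject(np.zeros((2, 4)), theta, -np.eye(2))
        with pytest.raises(ValueError):
            log_likelihood_subject(np.zeros((3, 4)), theta, np.eye(3))


class TestStability:
    def test_contraction_is_stable(self):
        ok, r = is_stable(VARCoefficients(0.5 * np.eye(3)[None]))
        assert ok and r == pytest.approx(0.5)

    def test_unit_root_is_not_stable(self):
        ok, r = is_stable(VARCoefficients(np.eye(2)[None]))
        assert not ok and r == pytest.approx(1.0)

    def test_lag2_scalar_matches_companion_eigenvalues(self):
        # oracle: largest root modulus of z^2 - 0.3 z - 0.3
        theta = VARCoefficients(np.array([[[0.3]], [[0.3]]]))
        expected = max(abs(np.roots([1.0, -0.3, -0.3])))
        assert is_stable(theta)[1] == pytest.approx(expected)


class TestAssembleSigma:
    def test_zero_loadings_gives_diagonal(self):
        fc = FactorCovariance(np.zeros((3, 2)), np.ones(2), np.array([1.0, 2.0, 3.0]))
        assert np.allclose(assemble_sigma(fc), np.diag([1.0, 2.0, 3.0]))

    def test_rank_one_arithmetic(self):
        fc = FactorCovariance(np.ones((2, 1)), np.ones(1), np.ones(2))
        assert np.allclose(assemble_sigma(fc), [[2.0, 1.0], [1.0, 2.0]])

    def test_eigenvalues_bounded_below_by_psi_and_cholesky(self, rng):
        for _ in range(20):
            fc = FactorCovariance(
                rng.standard_normal((5, 2)),
                rng.gamma(2.0, 1.0, 2),
                rng.gamma(2.0, 1.0, 5),
            )
            S = assemble_sigma(fc)
            np.linalg.cholesky(S)
            assert np.linalg.eigvalsh(S).min() >= fc.Psi.min() - 1e-10

    def test_rejects_nonpositive_scales(self):
        with pytest.raises(ValueError):
            FactorCovariance(np.zeros((2, 1)), np.zeros(1), np.ones(2))


class TestForecast:
    def test_zero_coefficients_forecast_zero(self, rng):
        theta = VARCoefficients(np.zeros((2, 3, 3)))
        path = forecast(rng.standard_normal((3, 10)), theta, h=4)
        assert np.allclose(path, 0.0)

    def test_scalar_geometric_recursion(self):
        theta = VARCoefficients(np.array([[[0.5]]]))
        path = forecast(np.array([[2.0, 1.0]]), theta, h=3)
        assert np.allclose(path, [[0.5, 0.25, 0.125]])

    def test_one_step_equals_lag_sum(self, rng):
        A = 0.2 * rng.standard_normal((2, 3, 3))
        theta = VARCoefficients(A)
        X = rng.standard_normal((3, 12))
        path = forecast(X, theta, h=1)
        expected = A[0] @ X[:, -1] + A[1] @ X[:, -2]
        assert np.allclose(path[:, 0], expected)

    def test_predictive_draw_mean_concentrates_on_point_path(self):
        rng_seed = 5
        theta = VARCoefficients(np.array([[[0.6]]]))
        X = np.array([[1.0, 0.8]])
        sigma = np.array([[0.5]])
        path, draws = forecast(X, theta, sigma=sigma, h=1, draws=10_000, rng=rng_seed)
        mc_se = np.sqrt(0.5 / 10_000)
        assert abs(draws[:, 0, 0].mean() - path[0, 0]) < 3 * mc_se

    def test_invalid_horizon(self):
        theta = VARCoefficients(np.zeros((1, 1, 1)))
        with pytest.raises(ValueError):
            forecast(np.ones((1, 3)), theta, h=0)


class TestDesignMatrix:
    def test_lagged_structure_with_zero_padding(self):
        X = np.arange(8.0).reshape(2, 4)
        Z = build_design(X, 2)
        assert Z.shape == (4, 4)
        assert np.allclose(Z[0], 0.0)
        assert np.allclose(Z[1, :2], X[:, 0]) and np.allclose(Z[1, 2:], 0.0)
        assert np.allclose(Z[3, :2], X[:, 2]) and np.allclose(Z[3, 2:], X[:, 1])


class TestPanelContainer:
    def test_rejects_inconsistent_dimension_and_short_series(self, rng):
        with pytest.raises(ValueError):
            PanelTimeSeries(
                [("a", rng.standard_normal((2, 10))), ("b", rng.standard_normal((3, 10)))]
            )
        with pytest.raises(ValueError):
            PanelTimeSeries([("a", rng.standard_normal((2, 2)))], n_lags=2)

    def test_csv_round_trip(self, tiny_panel, tmp_path):
        from pdpmvar import read_panel_csv, write_panel_csv

        path = tmp_path / "panel.csv"
        write_panel_csv(tiny_panel, path)
        back = read_panel_csv(path, n_lags=2)
        assert back.ids == tiny_panel.ids
        for (_, X0), (_, X1) in zip(tiny_panel, back):
            assert np.allclose(X0, X1)
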