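"""Exact VAR likelihood, stability check, covariance assembly, forecasting.

The likelihood is the product-of-conditional-densities form: for a D x T
series x_1..x_T with lag matrices A_1..A_K and residual covariance Sigma,

    L = prod_{t=1}^{T} N(x_t ; sum_{k=1}^{min(t-1,K)} A_k x_{t-k}, Sigma),

so x_1 has zero mean and early time points use only the lags that exist.
The intercept is fixed at zero.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .panel import FactorCovariance, VARCoefficients, build_design

__all__ = [
    "log_likelihood_subject",
    "is_stable",
    "companion_matrix",
    "assemble_sigma",
    "forecast",
    "posterior_forecast",
]

_STABILITY_TOL = 1e-10


def _chol_spd(sigma: np.ndarray) -> np.ndarray:
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if sigma.shape[0] != sigma.shape[1] or not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("sigma must be a symmetric square matrix")
    try:
        return linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - message only
        raise ValueError("sigma is not positive definite") from exc


def log_likelihood_subject(
    X: np.ndarray, theta: VARCoefficients, sigma: np.ndarray
) -> float:
    """Exact log-likelihood of one subject's D x T series.

    Raises ``ValueError`` for dimension mismatches or a non-SPD ``sigma``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D, T = X.shape
    if theta.D != D:
        raise ValueError(f"theta has D={theta.D} but series has D={D}")
    L = _chol_spd(sigma)
    if L.shape[0] != D:
        raise ValueError("sigma dimension does not match series")
    Z = build_design(X, theta.K)
    E = X.T - Z @ theta.stacked().T  # residuals, T x D
    W = linalg.solve_triangular(L, E.T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (T * D * np.log(2.0 * np.pi) + T * logdet + np.sum(W * W)))


def companion_matrix(theta: VARCoefficients) -> np.ndarray:
    """DK x DK companion form of a lag-K VAR."""
    D, K = theta.D, theta.K
    C = np.zeros((D * K, D * K))
    C[:D, :] = theta.stacked()
    if K > 1:
        C[D:, : D * (K - 1)] = np.eye(D * (K - 1))
    return C


def is_stable(theta: VARCoefficients) -> tuple[bool, float]:
    """Whether the VAR is stable, plus the companion spectral radius.

    Stability means the spectral radius is strictly below 1 (with a 1e-10
    tolerance at the boundary).
    """
    radius = float(np.max(np.abs(np.linalg.eigvals(companion_matrix(theta)))))
    return radius < 1.0 - _STABILITY_TOL, radius


def assemble_sigma(fc: FactorCovariance) -> np.ndarray:
    """Dense SPD covariance Gamma diag(Xi) Gamma' + diag(Psi)."""
    S = (fc.Gamma * fc.Xi) @ fc.Gamma.T + np.diag(fc.Psi)
    return 0.5 * (S + S.T)


def forecast(
    X: np.ndarray,
    theta: VARCoefficients,
    sigma: np.ndarray | None = None,
    h: int = 1,
    draws: int | None = None,
    rng: np.random.Generator | int | None = None,
):
    """h-step-ahead forecast from the end of a D x T series.

    The point path iterates the VAR mean recursion from the last K
    observations.  If ``draws`` is given, also returns ``draws`` sampled
    predictive paths (shape draws x D x h) that add N(0, Sigma) innovations
    at each step and feed them forward.
    """
    if h < 1:
        raise ValueError("forecast horizon h must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D, T = X.shape
    K = theta.K
    if T < K:
        raise ValueError("need at least K observations to forecast")
    A = theta.A

    def _step(history: np.ndarray) -> np.ndarray:
        # history holds the most recent K columns, newest last
        return sum(A[k] @ history[:, -(k + 1)] for k in range(K))

    hist = X[:, -K:].copy()
    path = np.empty((D, h))
    for j in range(h):
        nxt = _step(hist)
        path[:, j] = nxt
        hist = np.column_stack([hist[:, 1:], nxt]) if K > 1 else nxt[:, None]

    if draws is None:
        return path

    if sigma is None:
        raise ValueError("sigma is required for predictive draws")
    rng = np.random.default_rng(rng)
    L = _chol_spd(sigma)
    out = np.empty((draws, D, h))
    for s in range(draws):
        hist = X[:, -K:].copy()
        for j in range(h):
            nxt = _step(hist) + L @ rng.standard_normal(D)
            out[s, :, j] = nxt
            hist = np.column_stack([hist[:, 1:], nxt]) if K > 1 else nxt[:, None]
    return path, out


def posterior_forecast(draws_theta: np.ndarray, X: np.ndarray, h: int) -> np.ndarray:
    """Posterior point forecast: mean over retained draws of the per-draw
    VAR mean path.

    ``draws_theta`` has shape (n_draws, D, D*K) (stacked lag matrices per
    retained iteration).  Plug-in per-draw paths propagate parameter
    uncertainty into the point forecast.
    """
    n_draws = draws_theta.shape[0]
    D = draws_theta.shape[1]
    K = draws_theta.shape[2] // D
    acc = np.zeros((D, h))
    for s in range(n_draws):
        theta = VARCoefficients.from_stacked(draws_theta[s], K)
        acc += forecast(X, theta, h=h)
    return acc / n_draws
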