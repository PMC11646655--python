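"""Blocked Gibbs samplers for the product-of-DP mixture VAR family.

Three estimators share one sweep skeleton and differ only in how the
coefficient side clusters:

* :class:`PDPMVAR` — each subject's whole stack of lag matrices is one
  clustering unit;
* :class:`RowPDPMVAR` — each (subject, target-row) pair clusters
  independently, the atom being the stacked K rows for that target;
* :class:`LagPDPMVAR` — each (subject, lag) pair clusters independently,
  the atom being one D x D lag matrix.

The residual covariance always clusters at the subject level under a
parameter-expanded factor representation Sigma = Gamma diag(Xi) Gamma' +
diag(Psi).  Conditioning on the latent factors eta makes the residual
covariance diagonal, so coefficient rows decouple and each row update is
a DK-variate (or stacked, for the lag model) multivariate-normal draw
under the normal-scale-mixture representation of the Laplace base
measure.  Steps that use the eta-marginal likelihood (cluster
assignments) are immediately followed by a fresh draw of eta from its
full conditional, making each a valid blocked update of (labels, eta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .draws import PosteriorDraws
from .panel import FactorCovariance, PanelTimeSeries, VARCoefficients
from .sticks import (
    check_truncation,
    sample_assignments,
    sample_sticks,
    similarity_partition,
    stick_weights,
    posterior_similarity,
)
from .var import assemble_sigma

__all__ = [
    "HyperParams",
    "PDPMVAR",
    "RowPDPMVAR",
    "LagPDPMVAR",
    "SingleSubjectVAR",
    "run_pdpm_var",
    "run_rgpdpm_var",
    "run_lgpdpm_var",
    "sample_de_scales",
    "sample_factor_block",
]

logger = logging.getLogger(__name__)

_DE_ABS_FLOOR = 1e-10  # |a| floor in the inverse-Gaussian scale update
_TAU_FLOOR = 1e-12


@dataclass
class HyperParams:
    """Sampler hyperparameters; positivity is enforced on construction.

    ``lambda_de`` is the rate of the double-exponential (Laplace) base
    measure on coefficients; ``a_sigma``/``b_sigma`` are the Gamma
    shape/rate on the inverse idiosyncratic variances; ``n_factors`` is
    the rank B of the residual-covariance factor representation.
    """

    alpha_theta: float = 1.0
    alpha_sigma: float = 1.0
    lambda_de: float = 1.0
    a_sigma: float = 1.0
    b_sigma: float = 1.0
    n_factors: int = 5
    trunc: int = 20
    n_iter: int = 2000
    n_burn: int = 500
    thin: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("alpha_theta", "alpha_sigma", "lambda_de", "a_sigma", "b_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_factors < 0 or self.trunc < 1 or self.thin < 1:
            raise ValueError("n_factors >= 0, trunc >= 1, thin >= 1 required")
        if not self.n_burn < self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")


# --------------------------------------------------------------------------
# sufficient statistics and small shared pieces


class _SubjectStats:
    """Per-subject quantities fixed across the whole run."""

    __slots__ = ("Xt", "Z", "G", "Czx", "Sxx", "T")

    def __init__(self, X: np.ndarray, n_lags: int):
        from .panel import build_design

        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.Xt = X.T.copy()                      # T x D
        self.Z = build_design(X, n_lags)          # T x DK
        self.G = self.Z.T @ self.Z                # DK x DK
        self.Czx = self.Z.T @ self.Xt             # DK x D
        self.Sxx = self.Xt.T @ self.Xt            # D x D
        self.T = X.shape[1]


def _residual_gram(st: _SubjectStats, A: np.ndarray) -> np.ndarray:
    """E'E for residuals E = Xt - Z A', from cached cross-products."""
    CA = st.Czx.T @ A.T
    return st.Sxx - CA - CA.T + A @ st.G @ A.T


def _gauss_loglik_from_gram(EtE: np.ndarray, T: int, logdet: float, Lam: np.ndarray) -> float:
    D = EtE.shape[0]
    return -0.5 * (T * D * np.log(2.0 * np.pi) + T * logdet + float(np.sum(Lam * EtE)))


def _draw_mvn_from_precision(
    Q: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One draw from N(Q^{-1} b, Q^{-1}) via the Cholesky factor of Q."""
    L = linalg.cholesky(Q, lower=True)
    mean = linalg.cho_solve((L, True), b)
    z = rng.standard_normal(b.shape[0])
    return mean + linalg.solve_triangular(L.T, z, lower=False)


def sample_de_scales(
    coefficients: np.ndarray, lambda_de: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent variances of the normal-scale-mixture Laplace representation.

    Each coefficient a carries a variance tau with prior
    Exponential(lambda^2 / 2); the full conditional of 1/tau is
    inverse-Gaussian with mean lambda/|a| and shape lambda^2, so that
    marginally a ~ DE(lambda).  |a| is floored at 1e-10 to cap the mean.
    """
    if lambda_de <= 0:
        raise ValueError("lambda_de must be positive")
    a = np.abs(np.asarray(coefficients, dtype=float))
    mean = lambda_de / np.maximum(a, _DE_ABS_FLOOR)
    shape = lambda_de**2
    inv_tau = stats.invgauss.rvs(
        mu=mean / shape, scale=shape, size=a.shape, random_state=rng
    )
    return np.clip(1.0 / np.maximum(inv_tau, _TAU_FLOOR), _TAU_FLOOR, None)


def _prior_de_scales(shape, lambda_de: float, rng: np.random.Generator) -> np.ndarray:
    return np.maximum(rng.exponential(scale=2.0 / lambda_de**2, size=shape), _TAU_FLOOR)


# --------------------------------------------------------------------------
# mutable sampler state


@dataclass
class _State:
    # coefficient scale (layout depends on the sampler variant)
    th_atoms: np.ndarray
    tau: np.ndarray
    c_th: np.ndarray
    v_th: np.ndarray
    # covariance scale
    Gam: np.ndarray      # (H, D, B)
    Xi: np.ndarray       # (H, B)
    Psi: np.ndarray      # (H, D)
    c_sg: np.ndarray     # (n,)
    v_sg: np.ndarray     # (H,)
    # per-sweep caches
    eta: list = field(default_factory=list)      # per subject T x B
    W: list = field(default_factory=list)        # per subject Z' eta, DK x B
    sig_chol: np.ndarray | None = None           # (H, D, D)
    sig_lam: np.ndarray | None = None
    sig_logdet: np.ndarray | None = None


def sample_factor_block(
    members: list[int],
    residuals: list[np.ndarray],
    fc: FactorCovariance,
    hp: HyperParams,
    rng: np.random.Generator,
    weight: float = 1.0,
) -> tuple[FactorCovariance, list[np.ndarray]]:
    """One Gibbs pass over (eta, Gamma, Xi, Psi) for one covariance cluster.

    ``residuals`` holds each member subject's T x D matrix of residuals
    after removing the lag effects.  An empty cluster is refreshed from
    the base measure: standard-normal loadings, Gamma(1/2,1/2) precisions
    for Xi (the parameter expansion inducing Cauchy-type loadings), and
    Gamma(a_sigma, b_sigma) precisions for Psi.
    """
    D, B = fc.D, fc.B
    if not members:
        Gam = rng.standard_normal((D, B))
        Xi = 1.0 / np.maximum(rng.gamma(0.5, 2.0, size=B), 1e-12)
        Psi = 1.0 / np.maximum(rng.gamma(hp.a_sigma, 1.0 / hp.b_sigma, size=D), 1e-12)
        return FactorCovariance(Gam, Xi, Psi), []

    Gam, Xi, Psi = fc.Gamma.copy(), fc.Xi.copy(), fc.Psi.copy()
    w = weight

    # latent factors: shared posterior covariance within the cluster
    P = w * (Gam.T / Psi) @ Gam + np.diag(1.0 / Xi)
    Lp = linalg.cholesky(P, lower=True)
    Minv = linalg.cho_solve((Lp, True), (Gam / Psi[:, None]).T)  # B x D
    etas = []
    for R in residuals:
        mean = w * R @ Minv.T
        z = rng.standard_normal((R.shape[0], B))
        etas.append(mean + linalg.solve_triangular(Lp.T, z.T, lower=False).T)

    E = np.concatenate(residuals, axis=0)
    Heta = np.concatenate(etas, axis=0)
    Nt = E.shape[0]

    # loadings: row-wise B-variate normals under standard-normal priors
    HtH = Heta.T @ Heta
    Hr = Heta.T @ E  # B x D
    for d in range(D):
        Q = (w / Psi[d]) * HtH + np.eye(B)
        Gam[d] = _draw_mvn_from_precision(Q, (w / Psi[d]) * Hr[:, d], rng)

    # latent-factor variances under the Gamma(1/2, 1/2) parameter expansion
    inv_xi = rng.gamma(0.5 + 0.5 * w * Nt, 1.0 / (0.5 + 0.5 * w * np.sum(Heta**2, axis=0)))
    Xi = 1.0 / np.maximum(inv_xi, 1e-12)

    # idiosyncratic variances
    U = E - Heta @ Gam.T
    inv_psi = rng.gamma(
        hp.a_sigma + 0.5 * w * Nt, 1.0 / (hp.b_sigma + 0.5 * w * np.sum(U**2, axis=0))
    )
    Psi = 1.0 / np.maximum(inv_psi, 1e-12)
    return FactorCovariance(Gam, Xi, Psi), etas


# --------------------------------------------------------------------------
# estimators


class _BaseProductDPVAR(BaseEstimator):
    """Shared machinery for the three product-mixture VAR samplers."""

    _model_name = "base"

    def __init__(
        self,
        n_lags=1,
        trunc=20,
        alpha_theta=1.0,
        alpha_sigma=1.0,
        lambda_de=1.0,
        a_sigma=1.0,
        b_sigma=1.0,
        n_factors=5,
        n_iter=2000,
        n_burn=500,
        thin=1,
        init_clusters="silhouette",
        burnin_move_every=10,
        likelihood_weight=1.0,
        random_state=None,
        verbose=0,
    ):
        self.n_lags = n_lags
        self.trunc = trunc
        self.alpha_theta = alpha_theta
        self.alpha_sigma = alpha_sigma
        self.lambda_de = lambda_de
        self.a_sigma = a_sigma
        self.b_sigma = b_sigma
        self.n_factors = n_factors
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.thin = thin
        self.init_clusters = init_clusters
        self.burnin_move_every = burnin_move_every
        self.likelihood_weight = likelihood_weight
        self.random_state = random_state
        self.verbose = verbose

    # -- public API --------------------------------------------------------

    def fit(self, X, y=None):
        """Run the blocked Gibbs sampler on a panel.

        ``X`` may be a :class:`PanelTimeSeries` or a list of D x T arrays.
        """
        panel = self._as_panel(X)
        self._hp = self._hyper()
        rng = np.random.default_rng(self.random_state)
        stats_ = [_SubjectStats(Xi, self.n_lags) for Xi in panel.matrices()]
        self._D = panel.D
        self._n = panel.n_subjects
        # factor rank cannot exceed the outcome dimension
        self._B = min(self.n_factors, self._D)
        st = self._init_state(stats_, rng)
        self._refresh_sigma_cache(st)

        keep = range(self.n_burn, self.n_iter, self.thin)
        n_keep = len(keep)
        D, DK, n = self._D, self._D * self.n_lags, self._n
        rec_theta = np.empty((n_keep, n, D, DK))
        rec_sigma = np.empty((n_keep, n, D, D))
        rec_cth = np.empty((n_keep,) + st.c_th.shape, dtype=np.int64)
        rec_csg = np.empty((n_keep, n), dtype=np.int64)
        rec_vth = np.empty((n_keep,) + st.v_th.shape)
        rec_vsg = np.empty((n_keep, self.trunc))
        rec_ll = np.empty(n_keep)

        j = 0
        for it in range(self.n_iter):
            self._sweep(st, stats_, rng)
            if it < self.n_burn and (it + 1) % self.burnin_move_every == 0:
                # burn-in-only greedy split/merge relocation: restricted to
                # the adaptation phase, so the post-burn-in kernel is the
                # exact blocked Gibbs sampler
                self._burnin_moves(st, stats_, rng)
                self._sigma_moves(st, stats_, rng)
            if it >= self.n_burn and (it - self.n_burn) % self.thin == 0:
                A_all = self._subject_thetas(st)
                rec_theta[j] = A_all
                sig = np.stack(
                    [self._assembled_sigma(st, h) for h in range(self.trunc)]
                )
                rec_sigma[j] = sig[st.c_sg]
                rec_cth[j] = st.c_th
                rec_csg[j] = st.c_sg
                rec_vth[j] = st.v_th
                rec_vsg[j] = st.v_sg
                rec_ll[j] = self._total_loglik(st, stats_, A_all)
                if not np.isfinite(rec_ll[j]):
                    raise FloatingPointError(
                        "non-finite panel log-likelihood at a retained draw"
                    )
                j += 1
        check_truncation(np.bincount(st.c_sg, minlength=self.trunc))

        self.draws_ = PosteriorDraws(
            theta=rec_theta,
            sigma=rec_sigma,
            c_theta=rec_cth,
            c_sigma=rec_csg,
            v_theta=rec_vth,
            v_sigma=rec_vsg,
            loglik=rec_ll,
            n_lags=self.n_lags,
            subject_ids=panel.ids,
            model=self._model_name,
        )
        self.coef_mean_ = rec_theta.mean(axis=0)
        self.sigma_mean_ = rec_sigma.mean(axis=0)
        sim_th = posterior_similarity(self.draws_.theta_flat_labels())
        self.labels_theta_ = similarity_partition(sim_th)
        sim_sg = posterior_similarity(rec_csg)
        self.labels_sigma_ = similarity_partition(sim_sg)
        self.similarity_theta_ = sim_th
        self.similarity_sigma_ = sim_sg
        self.n_features_in_ = self._D
        self._panel = panel
        return self

    def predict(self, X=None, horizon: int = 5) -> np.ndarray:
        """Posterior point forecasts, (n_subjects, D, horizon).

        Averages the per-draw VAR mean path over retained draws, using
        each draw's subject-level coefficients.
        """
        from .var import forecast

        if not hasattr(self, "draws_"):
            raise RuntimeError("fit must be called before predict")
        panel = self._panel if X is None else self._as_panel(X)
        dr = self.draws_
        out = np.zeros((panel.n_subjects, panel.D, horizon))
        for s in range(dr.n_draws):
            for i, (_, Xi) in enumerate(panel):
                theta = VARCoefficients.from_stacked(dr.theta[s, i], self.n_lags)
                out[i] += forecast(Xi, theta, h=horizon)
        return out / dr.n_draws

    def score(self, X=None, y=None) -> float:
        """Mean retained-draw panel log-likelihood."""
        return float(np.mean(self.draws_.loglik))

    # -- shared helpers ----------------------------------------------------

    def _as_panel(self, X) -> PanelTimeSeries:
        if isinstance(X, PanelTimeSeries):
            if X.n_lags != self.n_lags:
                X = PanelTimeSeries(list(X.subjects), n_lags=self.n_lags)
            return X
        return PanelTimeSeries(
            [(str(i), np.asarray(Xi)) for i, Xi in enumerate(X)], n_lags=self.n_lags
        )

    def _hyper(self) -> HyperParams:
        return HyperParams(
            alpha_theta=self.alpha_theta,
            alpha_sigma=self.alpha_sigma,
            lambda_de=self.lambda_de,
            a_sigma=self.a_sigma,
            b_sigma=self.b_sigma,
            n_factors=self.n_factors,
            trunc=self.trunc,
            n_iter=self.n_iter,
            n_burn=self.n_burn,
            thin=self.thin,
        )

    def _assembled_sigma(self, st: _State, h: int) -> np.ndarray:
        return assemble_sigma(FactorCovariance(st.Gam[h], st.Xi[h], st.Psi[h]))

    def _refresh_sigma_cache(self, st: _State) -> None:
        H, D = self.trunc, self._D
        st.sig_chol = np.empty((H, D, D))
        st.sig_lam = np.empty((H, D, D))
        st.sig_logdet = np.empty(H)
        for h in range(H):
            S = self._assembled_sigma(st, h)
            L = linalg.cholesky(S, lower=True)
            st.sig_chol[h] = L
            st.sig_lam[h] = linalg.cho_solve((L, True), np.eye(D))
            st.sig_logdet[h] = 2.0 * np.sum(np.log(np.diag(L)))

    def _total_loglik(self, st, stats_, A_all) -> float:
        total = 0.0
        for i, s in enumerate(stats_):
            h = st.c_sg[i]
            EtE = _residual_gram(s, A_all[i])
            total += _gauss_loglik_from_gram(
                EtE, s.T, st.sig_logdet[h], st.sig_lam[h]
            )
        return total

    def _update_eta(self, st: _State, stats_, rng) -> None:
        """Draw latent factors for every subject given current parameters
        and cache W_i = Z_i' eta_i for the coefficient-row updates."""
        w = self.likelihood_weight
        B = self._B
        A_all = self._subject_thetas(st)
        st.eta = [None] * self._n
        st.W = [None] * self._n
        done = {}
        for i, s in enumerate(stats_):
            h = st.c_sg[i]
            if h not in done:
                Gam, Xi, Psi = st.Gam[h], st.Xi[h], st.Psi[h]
                P = w * (Gam.T / Psi) @ Gam + np.diag(1.0 / Xi)
                Lp = linalg.cholesky(P, lower=True)
                Minv = linalg.cho_solve((Lp, True), (Gam / Psi[:, None]).T)
                done[h] = (Lp, Minv)
            Lp, Minv = done[h]
            R = s.Xt - s.Z @ A_all[i].T
            mean = w * R @ Minv.T
            z = rng.standard_normal((s.T, B))
            eta = mean + linalg.solve_triangular(Lp.T, z.T, lower=False).T
            st.eta[i] = eta
            st.W[i] = s.Z.T @ eta

    def _update_sigma_side(self, st: _State, stats_, rng) -> None:
        """Covariance-scale assignments (eta-marginal likelihood), factor
        block, and stick update."""
        w = self.likelihood_weight
        H, n = self.trunc, self._n
        A_all = self._subject_thetas(st)
        resid = [s.Xt - s.Z @ A_all[i].T for i, s in enumerate(stats_)]

        log_lik = np.zeros((n, H))
        if w > 0:
            for i, s in enumerate(stats_):
                EtE = _residual_gram(s, A_all[i])
                for h in range(H):
                    log_lik[i, h] = w * _gauss_loglik_from_gram(
                        EtE, s.T, st.sig_logdet[h], st.sig_lam[h]
                    )
        logw = np.log(stick_weights(st.v_sg) + 1e-300)
        st.c_sg = sample_assignments(log_lik, logw, rng)

        hp = self._hp
        for h in range(H):
            members = [i for i in range(n) if st.c_sg[i] == h]
            fc = FactorCovariance(st.Gam[h], st.Xi[h], st.Psi[h])
            fc, etas = sample_factor_block(
                members, [resid[i] for i in members], fc, hp, rng, weight=w
            )
            st.Gam[h], st.Xi[h], st.Psi[h] = fc.Gamma, fc.Xi, fc.Psi
            for i, eta in zip(members, etas):
                st.eta[i] = eta
        self._refresh_sigma_cache(st)

        counts = np.bincount(st.c_sg, minlength=H)
        st.v_sg = sample_sticks(counts, self.alpha_sigma, rng).v

    # -- burn-in split/merge relocation ------------------------------------
    #
    # The blocked Gibbs kernel moves one clustering unit at a time, and
    # with hundreds of time points per unit the likelihood ratios between
    # established atoms are enormous: cluster splits and merges essentially
    # never occur after the chain settles.  During burn-in only, a greedy
    # pass proposes merging pairs of occupied clusters (accepted unless the
    # pooled atom loses more log-likelihood than a BIC-style allowance
    # 0.5 p log N) and splitting large clusters by 2-means on per-unit
    # least-squares features (accepted only when the gain exceeds the same
    # allowance).  Proposal atoms are ridge-pooled GLS means.

    def _bic_allowance(self, p_atom: int, members, stats_, obs_per_t=None) -> float:
        obs_per_t = self._D if obs_per_t is None else obs_per_t
        n_obs = sum(stats_[i].T for i in members) * obs_per_t
        return 0.5 * p_atom * np.log(max(n_obs, 2))

    def _burnin_moves(self, st: _State, stats_, rng) -> None:
        pass

    def _sigma_moves(self, st: _State, stats_, rng) -> None:
        """Burn-in-only covariance-scale split/merge relocation."""
        n, D, B = self._n, self._D, self._B
        A_all = self._subject_thetas(st)
        EtE = [_residual_gram(stats_[i], A_all[i]) for i in range(n)]
        p_atom = D * (B + 2)

        def chol_stats(S):
            L = linalg.cholesky(S, lower=True)
            return 2.0 * np.sum(np.log(np.diag(L))), linalg.cho_solve(
                (L, True), np.eye(D)
            )

        def ll(i, logdet, Lam):
            return _gauss_loglik_from_gram(EtE[i], stats_[i].T, logdet, Lam)

        def pooled_cov(members):
            S = sum(EtE[i] for i in members) / sum(stats_[i].T for i in members)
            return S + 1e-8 * np.trace(S) / D * np.eye(D)

        def factorize(S):
            # rank-B eigen-approximation as the proposal atom; the factor
            # block refines it in subsequent sweeps
            w, V = linalg.eigh(S)
            idx = np.argsort(w)[::-1][:B]
            Gam = V[:, idx] * np.sqrt(np.maximum(w[idx], 1e-10))
            Psi = np.maximum(np.diag(S) - np.sum(Gam**2, axis=1), 0.05 * np.diag(S))
            return Gam, np.ones(B), np.maximum(Psi, 1e-8)

        def cand_stats(S):
            # evaluate candidates through the same rank-B representation as
            # the standing atoms so approximation error cancels in deltas
            Gam, Xi, Psi = factorize(S)
            return chol_stats((Gam * Xi) @ Gam.T + np.diag(Psi))

        changed_any = False
        for _ in range(3):
            changed = False
            occ = list(np.unique(st.c_sg))
            cache = {
                h: chol_stats(self._assembled_sigma(st, h)) for h in occ
            }
            for ai in range(len(occ)):
                for bi in range(ai + 1, len(occ)):
                    h1, h2 = occ[ai], occ[bi]
                    m1 = np.where(st.c_sg == h1)[0]
                    m2 = np.where(st.c_sg == h2)[0]
                    if m1.size == 0 or m2.size == 0:
                        continue
                    both = np.concatenate([m1, m2])
                    Sc = pooled_cov(both)
                    ldc, Lc = cand_stats(Sc)
                    delta = sum(ll(i, ldc, Lc) for i in both) - (
                        sum(ll(i, *cache[h1]) for i in m1)
                        + sum(ll(i, *cache[h2]) for i in m2)
                    )
                    if delta > -self._bic_allowance(p_atom, both, stats_):
                        st.c_sg[m2] = h1
                        st.Gam[h1], st.Xi[h1], st.Psi[h1] = factorize(Sc)
                        cache[h1] = chol_stats(self._assembled_sigma(st, h1))
                        changed = changed_any = True
            free = [h for h in range(self.trunc) if not np.any(st.c_sg == h)]
            for h in list(np.unique(st.c_sg)):
                if not free:
                    break
                m = np.where(st.c_sg == h)[0]
                if m.size < 4:
                    continue
                feats = np.stack(
                    [np.log(np.diag(EtE[i]) / stats_[i].T) for i in m]
                )
                klab = KMeans(
                    n_clusters=2, n_init=3,
                    random_state=int(rng.integers(2**31 - 1)),
                ).fit_predict(feats)
                p1, p2 = m[klab == 0], m[klab == 1]
                if p1.size < 2 or p2.size < 2:
                    continue
                S1, S2 = pooled_cov(p1), pooled_cov(p2)
                ld1, L1 = cand_stats(S1)
                ld2, L2 = cand_stats(S2)
                ldh, Lh = chol_stats(self._assembled_sigma(st, h))
                delta = (
                    sum(ll(i, ld1, L1) for i in p1)
                    + sum(ll(i, ld2, L2) for i in p2)
                    - sum(ll(i, ldh, Lh) for i in m)
                )
                if delta > self._bic_allowance(p_atom, m, stats_):
                    h_new = free.pop()
                    st.c_sg[p2] = h_new
                    st.Gam[h], st.Xi[h], st.Psi[h] = factorize(S1)
                    st.Gam[h_new], st.Xi[h_new], st.Psi[h_new] = factorize(S2)
                    changed = changed_any = True
            if not changed:
                break
        if changed_any:
            self._refresh_sigma_cache(st)

    def _profile_ll(self, stats_i, A: np.ndarray) -> float:
        """Per-subject profile Gaussian log-likelihood -T/2 log det of the
        residual covariance MLE under coefficients ``A``.

        The residual covariance is profiled out, so a wrong coefficient
        atom cannot hide behind a compensating covariance fit — the
        failure mode of fixed-covariance comparisons when near-unit-root
        trajectories make coefficient errors low-rank.  Constants cancel
        in every accept/reject delta."""
        EtE = _residual_gram(stats_i, A) / stats_i.T
        EtE = EtE + 1e-10 * (np.trace(EtE) + 1.0) * np.eye(EtE.shape[0])
        sign, ld = np.linalg.slogdet(EtE)
        if sign <= 0:
            return -np.inf
        return -0.5 * stats_i.T * ld

    def _pooled_rows(self, members, stats_, psi_col, q_list, rows=None) -> np.ndarray:
        """Ridge-pooled GLS estimate of a stacked coefficient matrix for
        ``members``; ``psi_col[i, d]`` is the working noise variance and
        ``q_list[i]`` the (DK x D) factor-corrected cross-product targets."""
        D, DK = self._D, self._D * self.n_lags
        ridge = 0.5 * self.lambda_de**2
        rows = list(range(D)) if rows is None else list(rows)
        out = np.empty((len(rows), DK))
        for j, d in enumerate(rows):
            Q = ridge * np.eye(DK)
            b = np.zeros(DK)
            for i in members:
                Q += stats_[i].G / psi_col[i, d]
                b += q_list[i][:, d] / psi_col[i, d]
            out[j] = linalg.solve(Q, b, assume_a="pos")
        return out

    # -- hooks implemented per variant ------------------------------------

    def _subject_thetas(self, st: _State) -> np.ndarray:
        raise NotImplementedError

    def _init_state(self, stats_, rng) -> _State:
        raise NotImplementedError

    def _sweep(self, st: _State, stats_, rng) -> None:
        raise NotImplementedError

    # -- initialization helpers -------------------------------------------

    def _ls_estimates(self, stats_) -> np.ndarray:
        """Per-subject ridge least-squares stacked coefficients (n, D, DK).

        Also caches each subject's LS residual variances, the working
        noise scale for the relocation heuristics (coefficient precision
        is scale-free in the residual variance, so subjects are weighted
        by their own residual scale rather than a cluster's)."""
        out = np.empty((self._n, self._D, self._D * self.n_lags))
        self._psi_ls = np.empty((self._n, self._D))
        for i, s in enumerate(stats_):
            ridge = 1e-6 * (np.trace(s.G) / s.G.shape[0] + 1.0)
            out[i] = linalg.solve(
                s.G + ridge * np.eye(s.G.shape[0]), s.Czx, assume_a="pos"
            ).T
            self._psi_ls[i] = np.maximum(
                np.diag(_residual_gram(s, out[i])) / s.T, 1e-10
            )
        return out

    def _kmeans_labels(self, V: np.ndarray, k, rng) -> np.ndarray:
        """k-means initialization labels; ``k='silhouette'`` picks the
        cluster count in 2..8 by silhouette score.

        Data per clustering unit is long here, so likelihood ratios
        between well-separated atoms are enormous and the blocked sampler
        rarely merges or splits clusters after burn-in; starting from a
        data-supported partition matters.
        """
        n = V.shape[0]
        seed = int(rng.integers(2**31 - 1))
        if k == "silhouette":
            from sklearn.metrics import silhouette_score

            best_k, best_s = 1, -np.inf
            for kk in range(2, min(8, n - 1) + 1):
                km = KMeans(n_clusters=kk, n_init=5, random_state=seed)
                lab = km.fit_predict(V)
                if len(np.unique(lab)) < 2:
                    continue
                s = silhouette_score(V, lab)
                if s > best_s:
                    best_k, best_s = kk, s
            k = best_k
        k = max(1, min(int(k), n))
        if k == 1:
            return np.zeros(n, dtype=int)
        km = KMeans(n_clusters=k, n_init=5, random_state=seed)
        return km.fit_predict(V)

    def _init_k(self):
        if self.init_clusters == "silhouette":
            return "silhouette"
        return min(int(self.init_clusters), self.trunc)

    def _init_sigma_side(self, st_kwargs, stats_, ls, rng) -> None:
        """Initialize the covariance scale from per-subject residual
        covariances; loadings start at zero (diagonal covariance)."""
        H, D, B, n = self.trunc, self._D, self._B, self._n
        resid_cov = np.empty((n, D, D))
        for i, s in enumerate(stats_):
            resid_cov[i] = _residual_gram(s, ls[i]) / s.T
        labels = self._kmeans_labels(resid_cov.reshape(n, -1), self._init_k(), rng)
        Gam = np.zeros((H, D, B))
        Xi = np.ones((H, B))
        Psi = np.ones((H, D))
        for h in range(H):
            members = labels == h
            if members.any():
                Psi[h] = np.maximum(
                    np.mean(np.diagonal(resid_cov[members], axis1=1, axis2=2), axis=0),
                    1e-6,
                )
        st_kwargs.update(
            Gam=Gam, Xi=Xi, Psi=Psi, c_sg=labels.astype(np.int64),
            v_sg=sample_sticks(
                np.bincount(labels, minlength=H), self.alpha_sigma, rng
            ).v,
        )

    # -- ancestral prior draw (shared scaffolding) -------------------------

    def _prior_sigma_side(self, st_kwargs, rng) -> None:
        H, D, B = self.trunc, self._D, self._B
        hp = self._hp
        Gam = rng.standard_normal((H, D, B))
        Xi = 1.0 / np.maximum(rng.gamma(0.5, 2.0, size=(H, B)), 1e-12)
        Psi = 1.0 / np.maximum(
            rng.gamma(hp.a_sigma, 1.0 / hp.b_sigma, size=(H, D)), 1e-12
        )
        v_sg = np.clip(rng.beta(1.0, self.alpha_sigma, size=H), 1e-12, 1 - 1e-12)
        v_sg[-1] = 1.0
        pi = stick_weights(v_sg)
        c_sg = rng.choice(H, size=self._n, p=pi)
        st_kwargs.update(Gam=Gam, Xi=Xi, Psi=Psi, c_sg=c_sg, v_sg=v_sg)

    def _generate_panel(
        self, st: _State, T: int, rng: np.random.Generator
    ) -> list[np.ndarray]:
        """Draw (eta, X) jointly from the data model given the current
        parameters — used by prior-predictive checks and Geweke runs."""
        D, K, B = self._D, self.n_lags, self._B
        A_all = self._subject_thetas(st)
        out = []
        st.eta = []
        for i in range(self._n):
            A = np.stack(np.split(A_all[i], K, axis=1))  # K x D x D
            h = st.c_sg[i]
            Gam, Xi, Psi = st.Gam[h], st.Xi[h], st.Psi[h]
            eta = rng.standard_normal((T, B)) * np.sqrt(Xi)
            X = np.zeros((D, T))
            for t in range(T):
                mean = np.zeros(D)
                for k in range(1, min(t, K) + 1):
                    mean += A[k - 1] @ X[:, t - k]
                X[:, t] = mean + Gam @ eta[t] + rng.standard_normal(D) * np.sqrt(Psi)
            st.eta.append(eta)
            out.append(X)
        return out


class PDPMVAR(_BaseProductDPVAR):
    """Product-of-DP mixture of VARs: whole-coefficient-stack clustering.

    Subjects cluster jointly on their full set of lag matrices and,
    independently, on the residual covariance.  Coefficients carry a
    Laplace (double-exponential) base measure with rate ``lambda_de``,
    handled through its normal-exponential scale mixture so each
    coefficient row is conjugate.

    Parameters follow scikit-learn conventions; fitted attributes include
    ``draws_`` (the retained posterior), ``coef_mean_``, ``sigma_mean_``,
    ``labels_theta_`` and ``labels_sigma_`` (posterior-similarity point
    partitions).
    """

    _model_name = "pdpm_var"

    def _subject_thetas(self, st: _State) -> np.ndarray:
        return st.th_atoms[st.c_th]

    def _init_state(self, stats_, rng) -> _State:
        H, D, DK = self.trunc, self._D, self._D * self.n_lags
        ls = self._ls_estimates(stats_)
        self._ls_cache = ls
        labels = self._kmeans_labels(ls.reshape(self._n, -1), self._init_k(), rng)
        atoms = np.zeros((H, D, DK))
        for h in range(H):
            members = labels == h
            if members.any():
                atoms[h] = ls[members].mean(axis=0)
        kwargs = dict(
            th_atoms=atoms,
            tau=np.full((H, D, DK), 2.0 / self.lambda_de**2),
            c_th=labels.astype(np.int64),
            v_th=sample_sticks(
                np.bincount(labels, minlength=H), self.alpha_theta, rng
            ).v,
        )
        self._init_sigma_side(kwargs, stats_, ls, rng)
        return _State(**kwargs)

    def _prior_state(self, rng) -> _State:
        H, D, DK = self.trunc, self._D, self._D * self.n_lags
        tau = _prior_de_scales((H, D, DK), self.lambda_de, rng)
        atoms = rng.standard_normal((H, D, DK)) * np.sqrt(tau)
        v_th = np.clip(rng.beta(1.0, self.alpha_theta, size=H), 1e-12, 1 - 1e-12)
        v_th[-1] = 1.0
        c_th = rng.choice(H, size=self._n, p=stick_weights(v_th))
        kwargs = dict(th_atoms=atoms, tau=tau, c_th=c_th, v_th=v_th)
        self._prior_sigma_side(kwargs, rng)
        st = _State(**kwargs)
        return st

    def _sweep(self, st: _State, stats_, rng) -> None:
        w = self.likelihood_weight
        H, n, D = self.trunc, self._n, self._D

        # (a) coefficient-scale assignments, eta marginalized out
        log_lik = np.zeros((n, H))
        if w > 0:
            for i, s in enumerate(stats_):
                hs = st.c_sg[i]
                for h in range(H):
                    EtE = _residual_gram(s, st.th_atoms[h])
                    log_lik[i, h] = w * _gauss_loglik_from_gram(
                        EtE, s.T, st.sig_logdet[hs], st.sig_lam[hs]
                    )
        logw = np.log(stick_weights(st.v_th) + 1e-300)
        st.c_th = sample_assignments(log_lik, logw, rng)

        # (b) fresh latent factors, then per-cluster row updates
        self._update_eta(st, stats_, rng)
        for h in range(H):
            members = [i for i in range(n) if st.c_th[i] == h]
            if not members:
                st.tau[h] = _prior_de_scales(st.tau[h].shape, self.lambda_de, rng)
                st.th_atoms[h] = rng.standard_normal(st.th_atoms[h].shape) * np.sqrt(
                    st.tau[h]
                )
                continue
            for d in range(D):
                Q = np.diag(1.0 / st.tau[h, d])
                b = np.zeros(Q.shape[0])
                for i in members:
                    s = stats_[i]
                    psi = st.Psi[st.c_sg[i], d]
                    gam_d = st.Gam[st.c_sg[i], d]
                    Q += (w / psi) * s.G
                    b += (w / psi) * (s.Czx[:, d] - st.W[i] @ gam_d)
                st.th_atoms[h, d] = _draw_mvn_from_precision(Q, b, rng)

        # (c) Laplace latent scales and coefficient-scale sticks
        st.tau = sample_de_scales(st.th_atoms, self.lambda_de, rng)
        st.v_th = sample_sticks(
            np.bincount(st.c_th, minlength=H), self.alpha_theta, rng
        ).v

        # (d)-(f) covariance scale
        self._update_sigma_side(st, stats_, rng)

    def _burnin_moves(self, st: _State, stats_, rng) -> None:
        D, DK, n = self._D, self._D * self.n_lags, self._n
        q_list = [s.Czx for s in stats_]
        psi_col = self._psi_ls
        p_atom = D * DK

        def ll(i, A):
            return self._profile_ll(stats_[i], A)

        for _ in range(3):
            changed = False
            # merges
            occ = [h for h in np.unique(st.c_th)]
            for a_idx in range(len(occ)):
                for b_idx in range(a_idx + 1, len(occ)):
                    h1, h2 = occ[a_idx], occ[b_idx]
                    m1 = np.where(st.c_th == h1)[0]
                    m2 = np.where(st.c_th == h2)[0]
                    if m1.size == 0 or m2.size == 0:
                        continue
                    both = np.concatenate([m1, m2])
                    cand = self._pooled_rows(both, stats_, psi_col, q_list)
                    delta = sum(ll(i, cand) for i in both) - (
                        sum(ll(i, st.th_atoms[h1]) for i in m1)
                        + sum(ll(i, st.th_atoms[h2]) for i in m2)
                    )
                    if delta > -self._bic_allowance(p_atom, both, stats_):
                        st.c_th[m2] = h1
                        st.th_atoms[h1] = cand
                        changed = True
            # splits
            free = [h for h in range(self.trunc) if not np.any(st.c_th == h)]
            for h in np.unique(st.c_th):
                if not free:
                    break
                m = np.where(st.c_th == h)[0]
                if m.size < 4:
                    continue
                feats = self._ls_cache[m].reshape(m.size, -1)
                lab = KMeans(
                    n_clusters=2, n_init=3,
                    random_state=int(rng.integers(2**31 - 1)),
                ).fit_predict(feats)
                p1, p2 = m[lab == 0], m[lab == 1]
                if p1.size < 2 or p2.size < 2:
                    continue
                c1 = self._pooled_rows(p1, stats_, psi_col, q_list)
                c2 = self._pooled_rows(p2, stats_, psi_col, q_list)
                delta = (
                    sum(ll(i, c1) for i in p1)
                    + sum(ll(i, c2) for i in p2)
                    - sum(ll(i, st.th_atoms[h]) for i in m)
                )
                if delta > self._bic_allowance(p_atom, m, stats_):
                    h_new = free.pop()
                    st.c_th[p2] = h_new
                    st.th_atoms[h] = c1
                    st.th_atoms[h_new] = c2
                    changed = True
            if not changed:
                break


class RowPDPMVAR(_BaseProductDPVAR):
    """Row-generalized product mixture: each coefficient row clusters
    independently across subjects.

    The clustering unit is a (subject, target-variable) pair and the atom
    is the stacked K rows for that target (a DK-vector), so clusters of
    subjects may share identical coefficients for a subset of target
    variables only.  The covariance scale is as in :class:`PDPMVAR`.
    """

    _model_name = "rgpdpm_var"

    def _subject_thetas(self, st: _State) -> np.ndarray:
        # th_atoms: (D, H, DK); c_th: (n, D)
        n, D = st.c_th.shape
        out = np.empty((n, D, st.th_atoms.shape[2]))
        for d in range(D):
            out[:, d, :] = st.th_atoms[d, st.c_th[:, d]]
        return out

    def _init_state(self, stats_, rng) -> _State:
        H, D, DK, n = self.trunc, self._D, self._D * self.n_lags, self._n
        ls = self._ls_estimates(stats_)
        self._ls_cache = ls
        atoms = np.zeros((D, H, DK))
        labels = np.zeros((n, D), dtype=np.int64)
        for d in range(D):
            lab = self._kmeans_labels(ls[:, d, :], self._init_k(), rng)
            labels[:, d] = lab
            for h in range(H):
                members = lab == h
                if members.any():
                    atoms[d, h] = ls[members, d, :].mean(axis=0)
        v_th = np.empty((D, H))
        for d in range(D):
            v_th[d] = sample_sticks(
                np.bincount(labels[:, d], minlength=H), self.alpha_theta, rng
            ).v
        kwargs = dict(
            th_atoms=atoms,
            tau=np.full((D, H, DK), 2.0 / self.lambda_de**2),
            c_th=labels,
            v_th=v_th,
        )
        self._init_sigma_side(kwargs, stats_, ls, rng)
        return _State(**kwargs)

    def _prior_state(self, rng) -> _State:
        H, D, DK, n = self.trunc, self._D, self._D * self.n_lags, self._n
        tau = _prior_de_scales((D, H, DK), self.lambda_de, rng)
        atoms = rng.standard_normal((D, H, DK)) * np.sqrt(tau)
        v_th = np.clip(
            rng.beta(1.0, self.alpha_theta, size=(D, H)), 1e-12, 1 - 1e-12
        )
        v_th[:, -1] = 1.0
        c_th = np.empty((n, D), dtype=np.int64)
        for d in range(D):
            c_th[:, d] = rng.choice(H, size=n, p=stick_weights(v_th[d]))
        kwargs = dict(th_atoms=atoms, tau=tau, c_th=c_th, v_th=v_th)
        self._prior_sigma_side(kwargs, rng)
        return _State(**kwargs)

    def _sweep(self, st: _State, stats_, rng) -> None:
        w = self.likelihood_weight
        H, n, D = self.trunc, self._n, self._D

        # (a) latent factors first: conditioning on eta makes Psi diagonal,
        # so row assignments and row updates decouple across targets
        self._update_eta(st, stats_, rng)

        # (b) row-level assignments and atom updates, one target at a time
        for d in range(D):
            A_d = st.th_atoms[d]  # H x DK
            log_lik = np.zeros((n, H))
            if w > 0:
                for i, s in enumerate(stats_):
                    psi = st.Psi[st.c_sg[i], d]
                    gam_d = st.Gam[st.c_sg[i], d]
                    q = s.Czx[:, d] - st.W[i] @ gam_d
                    quad = np.einsum("hj,jk,hk->h", A_d, s.G, A_d)
                    log_lik[i] = (w / psi) * (A_d @ q - 0.5 * quad)
            logw = np.log(stick_weights(st.v_th[d]) + 1e-300)
            st.c_th[:, d] = sample_assignments(log_lik, logw, rng)

            for h in range(H):
                members = [i for i in range(n) if st.c_th[i, d] == h]
                if not members:
                    st.tau[d, h] = _prior_de_scales(
                        st.tau[d, h].shape, self.lambda_de, rng
                    )
                    st.th_atoms[d, h] = rng.standard_normal(
                        st.th_atoms[d, h].shape
                    ) * np.sqrt(st.tau[d, h])
                    continue
                Q = np.diag(1.0 / st.tau[d, h])
                b = np.zeros(Q.shape[0])
                for i in members:
                    s = stats_[i]
                    psi = st.Psi[st.c_sg[i], d]
                    gam_d = st.Gam[st.c_sg[i], d]
                    Q += (w / psi) * s.G
                    b += (w / psi) * (s.Czx[:, d] - st.W[i] @ gam_d)
                st.th_atoms[d, h] = _draw_mvn_from_precision(Q, b, rng)

        # (c) Laplace scales and per-row sticks
        st.tau = sample_de_scales(st.th_atoms, self.lambda_de, rng)
        for d in range(D):
            st.v_th[d] = sample_sticks(
                np.bincount(st.c_th[:, d], minlength=H), self.alpha_theta, rng
            ).v

        # (d)-(f) covariance scale
        self._update_sigma_side(st, stats_, rng)

    def _burnin_moves(self, st: _State, stats_, rng) -> None:
        # row-wise relocation under the per-subject profile metric with
        # the candidate row substituted into the current stacked matrix
        D, DK, n = self._D, self._D * self.n_lags, self._n
        q_list = [s.Czx for s in stats_]
        psi_col = self._psi_ls
        A_all = self._subject_thetas(st)

        def ll_row(i, d, a):
            A = A_all[i].copy()
            A[d] = a
            return self._profile_ll(stats_[i], A)

        for d in range(D):
            lab = st.c_th[:, d]
            for _ in range(3):
                changed = False
                occ = list(np.unique(lab))
                for ai in range(len(occ)):
                    for bi in range(ai + 1, len(occ)):
                        h1, h2 = occ[ai], occ[bi]
                        m1 = np.where(lab == h1)[0]
                        m2 = np.where(lab == h2)[0]
                        if m1.size == 0 or m2.size == 0:
                            continue
                        both = np.concatenate([m1, m2])
                        cand = self._pooled_rows(both, stats_, psi_col, q_list, rows=[d])[0]
                        delta = sum(ll_row(i, d, cand) for i in both) - (
                            sum(ll_row(i, d, st.th_atoms[d, h1]) for i in m1)
                            + sum(ll_row(i, d, st.th_atoms[d, h2]) for i in m2)
                        )
                        if delta > -self._bic_allowance(DK, both, stats_, obs_per_t=1):
                            lab[m2] = h1
                            st.th_atoms[d, h1] = cand
                            A_all[both, d, :] = cand
                            changed = True
                free = [h for h in range(self.trunc) if not np.any(lab == h)]
                for h in list(np.unique(lab)):
                    if not free:
                        break
                    m = np.where(lab == h)[0]
                    if m.size < 4:
                        continue
                    feats = self._ls_cache[m, d, :]
                    klab = KMeans(
                        n_clusters=2, n_init=3,
                        random_state=int(rng.integers(2**31 - 1)),
                    ).fit_predict(feats)
                    p1, p2 = m[klab == 0], m[klab == 1]
                    if p1.size < 2 or p2.size < 2:
                        continue
                    c1 = self._pooled_rows(p1, stats_, psi_col, q_list, rows=[d])[0]
                    c2 = self._pooled_rows(p2, stats_, psi_col, q_list, rows=[d])[0]
                    delta = (
                        sum(ll_row(i, d, c1) for i in p1)
                        + sum(ll_row(i, d, c2) for i in p2)
                        - sum(ll_row(i, d, st.th_atoms[d, h]) for i in m)
                    )
                    if delta > self._bic_allowance(DK, m, stats_, obs_per_t=1):
                        h_new = free.pop()
                        lab[p2] = h_new
                        st.th_atoms[d, h] = c1
                        st.th_atoms[d, h_new] = c2
                        A_all[p1, d, :] = c1
                        A_all[p2, d, :] = c2
                        changed = True
                if not changed:
                    break


class LagPDPMVAR(_BaseProductDPVAR):
    """Lag-generalized product mixture: each lag matrix clusters
    independently across subjects.

    The clustering unit is a (subject, lag) pair with a D x D atom per
    lag.  Because subjects mix lag-cluster memberships, each coefficient
    row is updated jointly across all occupied clusters of that row's lag
    blocks.  With ``n_lags=1`` the model coincides with :class:`PDPMVAR`.
    """

    _model_name = "lgpdpm_var"

    def _subject_thetas(self, st: _State) -> np.ndarray:
        # th_atoms: (K, H, D, D); c_th: (n, K)
        n, K = st.c_th.shape
        D = st.th_atoms.shape[2]
        out = np.empty((n, D, D * K))
        for k in range(K):
            out[:, :, k * D : (k + 1) * D] = st.th_atoms[k, st.c_th[:, k]]
        return out

    def _init_state(self, stats_, rng) -> _State:
        H, D, K, n = self.trunc, self._D, self.n_lags, self._n
        ls = self._ls_estimates(stats_)
        self._ls_cache = ls
        atoms = np.zeros((K, H, D, D))
        labels = np.zeros((n, K), dtype=np.int64)
        v_th = np.empty((K, H))
        # initialize lag partitions as coarsenings of a joint partition:
        # subject-level lag blocks are too noisy to cluster directly, but
        # each joint cluster's mean lag block is well estimated
        joint = self._kmeans_labels(ls.reshape(n, -1), self._init_k(), rng)
        groups = np.unique(joint)
        for k in range(K):
            block = ls[:, :, k * D : (k + 1) * D].reshape(n, -1)
            if groups.size > 2:
                reps = np.stack([block[joint == g].mean(axis=0) for g in groups])
                group_lab = self._kmeans_labels(reps, self._init_k(), rng)
                lab = group_lab[np.searchsorted(groups, joint)]
            else:
                lab = self._kmeans_labels(block, self._init_k(), rng)
            labels[:, k] = lab
            for h in range(H):
                members = lab == h
                if members.any():
                    atoms[k, h] = ls[members][:, :, k * D : (k + 1) * D].mean(axis=0)
            v_th[k] = sample_sticks(
                np.bincount(lab, minlength=H), self.alpha_theta, rng
            ).v
        kwargs = dict(
            th_atoms=atoms,
            tau=np.full((K, H, D, D), 2.0 / self.lambda_de**2),
            c_th=labels,
            v_th=v_th,
        )
        self._init_sigma_side(kwargs, stats_, ls, rng)
        return _State(**kwargs)

    def _prior_state(self, rng) -> _State:
        H, D, K, n = self.trunc, self._D, self.n_lags, self._n
        tau = _prior_de_scales((K, H, D, D), self.lambda_de, rng)
        atoms = rng.standard_normal((K, H, D, D)) * np.sqrt(tau)
        v_th = np.clip(
            rng.beta(1.0, self.alpha_theta, size=(K, H)), 1e-12, 1 - 1e-12
        )
        v_th[:, -1] = 1.0
        c_th = np.empty((n, K), dtype=np.int64)
        for k in range(K):
            c_th[:, k] = rng.choice(H, size=n, p=stick_weights(v_th[k]))
        kwargs = dict(th_atoms=atoms, tau=tau, c_th=c_th, v_th=v_th)
        self._prior_sigma_side(kwargs, rng)
        return _State(**kwargs)

    def _sweep(self, st: _State, stats_, rng) -> None:
        w = self.likelihood_weight
        H, n, D, K = self.trunc, self._n, self._D, self.n_lags

        # (a) per-(subject, lag) assignments, eta marginalized out
        for k in range(K):
            log_lik = np.zeros((n, H))
            if w > 0:
                A_all = self._subject_thetas(st)
                for i, s in enumerate(stats_):
                    hs = st.c_sg[i]
                    A = A_all[i].copy()
                    for h in range(H):
                        A[:, k * D : (k + 1) * D] = st.th_atoms[k, h]
                        EtE = _residual_gram(s, A)
                        log_lik[i, h] = w * _gauss_loglik_from_gram(
                            EtE, s.T, st.sig_logdet[hs], st.sig_lam[hs]
                        )
            logw = np.log(stick_weights(st.v_th[k]) + 1e-300)
            st.c_th[:, k] = sample_assignments(log_lik, logw, rng)

        # (b) fresh latent factors, then joint row updates across all
        # occupied (lag, cluster) atoms
        self._update_eta(st, stats_, rng)
        occupied = [np.unique(st.c_th[:, k]) for k in range(K)]
        slots = {}
        for k in range(K):
            for h in occupied[k]:
                slots[(k, int(h))] = len(slots)
        P = len(slots) * D
        for d in range(D):
            Q = np.zeros((P, P))
            b = np.zeros(P)
            for (k, h), s_idx in slots.items():
                sl = slice(s_idx * D, (s_idx + 1) * D)
                Q[sl, sl] += np.diag(1.0 / st.tau[k, h, d])
            for i, s in enumerate(stats_):
                psi = st.Psi[st.c_sg[i], d]
                gam_d = st.Gam[st.c_sg[i], d]
                q_i = s.Czx[:, d] - st.W[i] @ gam_d
                idx = [slots[(k, int(st.c_th[i, k]))] for k in range(K)]
                for k in range(K):
                    sl_k = slice(idx[k] * D, (idx[k] + 1) * D)
                    bk = slice(k * D, (k + 1) * D)
                    b[sl_k] += (w / psi) * q_i[bk]
                    for k2 in range(K):
                        sl_k2 = slice(idx[k2] * D, (idx[k2] + 1) * D)
                        bk2 = slice(k2 * D, (k2 + 1) * D)
                        Q[sl_k, sl_k2] += (w / psi) * s.G[bk, bk2]
            beta = _draw_mvn_from_precision(Q, b, rng)
            for (k, h), s_idx in slots.items():
                st.th_atoms[k, h, d] = beta[s_idx * D : (s_idx + 1) * D]
        # refresh unoccupied atoms from the base measure
        for k in range(K):
            for h in range(H):
                if h not in occupied[k]:
                    st.tau[k, h] = _prior_de_scales(
                        st.tau[k, h].shape, self.lambda_de, rng
                    )
                    st.th_atoms[k, h] = rng.standard_normal(
                        st.th_atoms[k, h].shape
                    ) * np.sqrt(st.tau[k, h])

        # (c) Laplace scales and per-lag sticks
        st.tau = sample_de_scales(st.th_atoms, self.lambda_de, rng)
        for k in range(K):
            st.v_th[k] = sample_sticks(
                np.bincount(st.c_th[:, k], minlength=H), self.alpha_theta, rng
            ).v

        # (d)-(f) covariance scale
        self._update_sigma_side(st, stats_, rng)

    def _burnin_moves(self, st: _State, stats_, rng) -> None:
        D, K, n = self._D, self.n_lags, self._n
        q_list = [s.Czx for s in stats_]
        psi_col = self._psi_ls
        p_atom = D * D

        def ll_with_block(i, k, block):
            # profile metric with the lag-k block replaced by the candidate
            A = self._subject_thetas(st)[i].copy()
            A[:, k * D : (k + 1) * D] = block
            return self._profile_ll(stats_[i], A)

        def pooled_block(members, k):
            # GLS pooled lag-k matrix with other lags held at current values
            bk = slice(k * D, (k + 1) * D)
            ridge = 0.5 * self.lambda_de**2
            A_all = self._subject_thetas(st)
            out = np.empty((D, D))
            for d in range(D):
                Q = ridge * np.eye(D)
                b = np.zeros(D)
                for i in members:
                    s = stats_[i]
                    resid = q_list[i][bk, d].copy()
                    for k2 in range(K):
                        if k2 != k:
                            bk2 = slice(k2 * D, (k2 + 1) * D)
                            resid -= s.G[bk, bk2] @ A_all[i, d, bk2]
                    Q += s.G[bk, bk] / psi_col[i, d]
                    b += resid / psi_col[i, d]
                out[d] = linalg.solve(Q, b, assume_a="pos")
            return out

        for k in range(K):
            lab = st.c_th[:, k]
            for _ in range(2):
                changed = False
                occ = list(np.unique(lab))
                for ai in range(len(occ)):
                    for bi in range(ai + 1, len(occ)):
                        h1, h2 = occ[ai], occ[bi]
                        m1 = np.where(lab == h1)[0]
                        m2 = np.where(lab == h2)[0]
                        if m1.size == 0 or m2.size == 0:
                            continue
                        both = np.concatenate([m1, m2])
                        cand = pooled_block(both, k)
                        delta = sum(ll_with_block(i, k, cand) for i in both) - (
                            sum(ll_with_block(i, k, st.th_atoms[k, h1]) for i in m1)
                            + sum(ll_with_block(i, k, st.th_atoms[k, h2]) for i in m2)
                        )
                        if delta > -self._bic_allowance(p_atom, both, stats_):
                            lab[m2] = h1
                            st.th_atoms[k, h1] = cand
                            changed = True
                free = [h for h in range(self.trunc) if not np.any(lab == h)]
                for h in list(np.unique(lab)):
                    if not free:
                        break
                    m = np.where(lab == h)[0]
                    if m.size < 4:
                        continue
                    feats = self._ls_cache[m][:, :, k * D : (k + 1) * D].reshape(
                        m.size, -1
                    )
                    klab = KMeans(
                        n_clusters=2, n_init=3,
                        random_state=int(rng.integers(2**31 - 1)),
                    ).fit_predict(feats)
                    p1, p2 = m[klab == 0], m[klab == 1]
                    if p1.size < 2 or p2.size < 2:
                        continue
                    c1 = pooled_block(p1, k)
                    c2 = pooled_block(p2, k)
                    delta = (
                        sum(ll_with_block(i, k, c1) for i in p1)
                        + sum(ll_with_block(i, k, c2) for i in p2)
                        - sum(ll_with_block(i, k, st.th_atoms[k, h]) for i in m)
                    )
                    if delta > self._bic_allowance(p_atom, m, stats_):
                        h_new = free.pop()
                        lab[p2] = h_new
                        st.th_atoms[k, h] = c1
                        st.th_atoms[k, h_new] = c2
                        changed = True
                if not changed:
                    break


class SingleSubjectVAR(_BaseProductDPVAR):
    """Per-subject parametric Bayesian VAR baseline.

    Fits each subject independently with a single cluster at both scales
    (truncation 1), i.e. no pooling across subjects — the plain
    single-subject comparator for the product-mixture models.
    """

    _model_name = "ss_var"

    def fit(self, X, y=None):
        panel = self._as_panel(X)
        rng = np.random.default_rng(self.random_state)
        subs = []
        for sid, Xi in panel:
            est = PDPMVAR(**{**self.get_params(), "trunc": 1, "init_clusters": 1})
            est.set_params(random_state=int(rng.integers(2**31 - 1)))
            est.fit(PanelTimeSeries([(sid, Xi)], n_lags=self.n_lags))
            subs.append(est.draws_)
        d0 = subs[0]
        self.draws_ = PosteriorDraws(
            theta=np.concatenate([d.theta for d in subs], axis=1),
            sigma=np.concatenate([d.sigma for d in subs], axis=1),
            c_theta=np.stack(
                [np.full(d0.theta.shape[0], i) for i in range(len(subs))], axis=1
            ),
            c_sigma=np.stack(
                [np.full(d0.theta.shape[0], i) for i in range(len(subs))], axis=1
            ),
            v_theta=d0.v_theta,
            v_sigma=d0.v_sigma,
            loglik=np.sum([d.loglik for d in subs], axis=0),
            n_lags=self.n_lags,
            subject_ids=panel.ids,
            model=self._model_name,
        )
        self.coef_mean_ = self.draws_.theta_mean()
        self.sigma_mean_ = self.draws_.sigma_mean()
        self.labels_theta_ = np.arange(panel.n_subjects)
        self.labels_sigma_ = np.arange(panel.n_subjects)
        self.n_features_in_ = panel.D
        self._panel = panel
        return self


# --------------------------------------------------------------------------
# thin functional wrappers


def _wrap(cls, panel: PanelTimeSeries, hp: HyperParams, **kw) -> PosteriorDraws:
    est = cls(
        n_lags=panel.n_lags,
        trunc=hp.trunc,
        alpha_theta=hp.alpha_theta,
        alpha_sigma=hp.alpha_sigma,
        lambda_de=hp.lambda_de,
        a_sigma=hp.a_sigma,
        b_sigma=hp.b_sigma,
        n_factors=hp.n_factors,
        n_iter=hp.n_iter,
        n_burn=hp.n_burn,
        thin=hp.thin,
        random_state=hp.seed,
        **kw,
    )
    est.fit(panel)
    return est.draws_


def run_pdpm_var(panel: PanelTimeSeries, hp: HyperParams, **kw) -> PosteriorDraws:
    """Fit the whole-coefficient-stack product mixture VAR."""
    return _wrap(PDPMVAR, panel, hp, **kw)


def run_rgpdpm_var(panel: PanelTimeSeries, hp: HyperParams, **kw) -> PosteriorDraws:
    """Fit the row-generalized product mixture VAR."""
    return _wrap(RowPDPMVAR, panel, hp, **kw)


def run_lgpdpm_var(panel: PanelTimeSeries, hp: HyperParams, **kw) -> PosteriorDraws:
    """Fit the lag-generalized product mixture VAR."""
    return _wrap(LagPDPMVAR, panel, hp, **kw)
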