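"""DP mixtures for independent multivariate data.

Three samplers over x_i ~ N(mu_i, Sigma_i):

* :class:`DPMixture` — the standard location-scale DP mixture: one label
  per sample, atoms (mu_h, Sigma_h) drawn jointly from a
  normal/inverse-Wishart base measure;
* :class:`ProductDPMixture` — independent DPs on the mean vector and on
  the covariance, so the two cluster structures are decoupled;
* :class:`CoordinateProductDPMixture` — independent DPs on *each
  coordinate* of the mean plus one on the covariance, the most granular
  mean-clustering variant.

Base-measure hyperparameters are set empirically from the data moments.
All three use the same truncated stick-breaking blocked Gibbs scheme as
the VAR samplers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .sticks import (
    posterior_similarity,
    sample_assignments,
    sample_sticks,
    similarity_partition,
    stick_weights,
)

__all__ = [
    "IidDraws",
    "DPMixture",
    "ProductDPMixture",
    "CoordinateProductDPMixture",
    "run_dpm_iid",
    "run_pdpm_iid",
    "run_gpdpm_iid",
]


@dataclass
class IidDraws:
    """Retained draws of an independent-data mixture run."""

    mu: np.ndarray            # (n_draws, n, D) subject-level means
    c_mu: np.ndarray          # (n_draws, n) or (n_draws, n, D)
    c_sigma: np.ndarray       # (n_draws, n)
    loglik: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    def mu_flat_labels(self) -> np.ndarray:
        return self.c_mu.reshape(self.c_mu.shape[0], -1)


def _mvn_logpdf_grid(X, mus, sigmas):
    """log N(x_i; mu_h, Sigma_h) for all i, h -> (n, H)."""
    n, D = X.shape
    H = mus.shape[0]
    out = np.empty((n, H))
    for h in range(H):
        L = linalg.cholesky(sigmas[h], lower=True)
        W = linalg.solve_triangular(L, (X - mus[h]).T, lower=True)
        out[:, h] = -0.5 * (
            D * np.log(2 * np.pi)
            + 2 * np.sum(np.log(np.diag(L)))
            + np.sum(W * W, axis=0)
        )
    return out


class _BaseIidMixture(BaseEstimator):
    def __init__(
        self,
        trunc=20,
        alpha_mu=1.0,
        alpha_sigma=1.0,
        n_iter=1000,
        n_burn=300,
        thin=1,
        init_clusters=10,
        random_state=None,
    ):
        self.trunc = trunc
        self.alpha_mu = alpha_mu
        self.alpha_sigma = alpha_sigma
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.thin = thin
        self.init_clusters = init_clusters
        self.random_state = random_state

    def _empirical_base(self, X):
        """Empirical-Bayes base-measure hyperparameters from data moments."""
        n, D = X.shape
        var = X.var(axis=0)
        if np.any(var < 1e-12):
            import warnings

            warnings.warn("degenerate data: a column has (near) zero variance")
        self._m0 = X.mean(axis=0)
        self._s0 = np.maximum(var, 1e-8) * 4.0  # diffuse mean-base variance
        self._nu0 = D + 2
        S = np.cov(X.T) if D > 1 else np.atleast_2d(np.var(X))
        self._S0 = S + 1e-6 * np.eye(D)

    def _draw_sigma_atom(self, rng, nu=None, S=None):
        nu = self._nu0 if nu is None else nu
        S = self._S0 if S is None else S
        return stats.invwishart.rvs(df=nu, scale=S, random_state=rng)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be an n x D matrix with n >= 2")
        rng = np.random.default_rng(self.random_state)
        self._empirical_base(X)
        state = self._init_state(X, rng)
        keep = range(self.n_burn, self.n_iter, self.thin)
        rec_mu = np.empty((len(keep), X.shape[0], X.shape[1]))
        rec_cmu, rec_csg, rec_ll = [], [], []
        j = 0
        for it in range(self.n_iter):
            self._sweep(state, X, rng)
            if it >= self.n_burn and (it - self.n_burn) % self.thin == 0:
                rec_mu[j] = self._subject_means(state)
                rec_cmu.append(np.copy(state["c_mu"]))
                rec_csg.append(np.copy(state["c_sg"]))
                rec_ll.append(self._loglik(state, X))
                j += 1
        self.draws_ = IidDraws(
            mu=rec_mu,
            c_mu=np.stack(rec_cmu),
            c_sigma=np.stack(rec_csg),
            loglik=np.asarray(rec_ll),
        )
        self.labels_mu_ = similarity_partition(
            posterior_similarity(self.draws_.mu_flat_labels())
        )
        self.labels_sigma_ = similarity_partition(
            posterior_similarity(self.draws_.c_sigma)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _loglik(self, st, X):
        mus = self._subject_means(st)
        sigmas = st["sg_atoms"][st["c_sg"]]
        total = 0.0
        for i in range(X.shape[0]):
            L = linalg.cholesky(sigmas[i], lower=True)
            w = linalg.solve_triangular(L, X[i] - mus[i], lower=True)
            total += -0.5 * (
                X.shape[1] * np.log(2 * np.pi)
                + 2 * np.sum(np.log(np.diag(L)))
                + w @ w
            )
        return total


class DPMixture(_BaseIidMixture):
    """Standard DP location-scale mixture: shared (mu, Sigma) clusters."""

    def _init_state(self, X, rng):
        H = self.trunc
        n, D = X.shape
        k = max(1, min(self.init_clusters, H, n))
        labels = (
            KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31 - 1)))
            .fit_predict(X)
            if k > 1
            else np.zeros(n, dtype=int)
        )
        mu_atoms = np.tile(self._m0, (H, 1))
        sg_atoms = np.tile(self._S0, (H, 1, 1))
        for h in range(H):
            m = labels == h
            if m.any():
                mu_atoms[h] = X[m].mean(axis=0)
        v = sample_sticks(np.bincount(labels, minlength=H), self.alpha_mu, rng).v
        return dict(
            mu_atoms=mu_atoms, sg_atoms=sg_atoms,
            c_mu=labels.astype(np.int64), c_sg=labels.astype(np.int64), v=v,
        )

    def _subject_means(self, st):
        return st["mu_atoms"][st["c_mu"]]

    def _sweep(self, st, X, rng):
        H = self.trunc
        n, D = X.shape
        ll = _mvn_logpdf_grid(X, st["mu_atoms"], st["sg_atoms"])
        logw = np.log(stick_weights(st["v"]) + 1e-300)
        labels = sample_assignments(ll, logw, rng)
        st["c_mu"] = labels
        st["c_sg"] = labels  # DPM constrains the two scales to agree
        for h in range(H):
            m = labels == h
            if not m.any():
                st["sg_atoms"][h] = self._draw_sigma_atom(rng)
                st["mu_atoms"][h] = self._m0 + np.sqrt(self._s0) * rng.standard_normal(D)
                continue
            Xh = X[m]
            # mu | Sigma: normal base N(m0, diag(s0))
            Lam = np.linalg.inv(st["sg_atoms"][h])
            Q = np.diag(1.0 / self._s0) + Xh.shape[0] * Lam
            b = self._m0 / self._s0 + Lam @ Xh.sum(axis=0)
            L = linalg.cholesky(Q, lower=True)
            mean = linalg.cho_solve((L, True), b)
            st["mu_atoms"][h] = mean + linalg.solve_triangular(
                L.T, rng.standard_normal(D), lower=False
            )
            # Sigma | mu: inverse-Wishart conjugate update
            Ec = Xh - st["mu_atoms"][h]
            st["sg_atoms"][h] = self._draw_sigma_atom(
                rng, nu=self._nu0 + Xh.shape[0], S=self._S0 + Ec.T @ Ec
            )
        st["v"] = sample_sticks(np.bincount(labels, minlength=H), self.alpha_mu, rng).v


class _ProductBase(_BaseIidMixture):
    """Shared covariance-scale machinery for the product mixtures."""

    def _init_sigma(self, X, labels_hint, rng, st):
        H = self.trunc
        st["sg_atoms"] = np.tile(self._S0, (H, 1, 1))
        st["c_sg"] = labels_hint.astype(np.int64)
        st["v_sg"] = sample_sticks(
            np.bincount(labels_hint, minlength=H), self.alpha_sigma, rng
        ).v

    def _update_sigma_scale(self, st, X, rng):
        H = self.trunc
        mus = self._subject_means(st)
        E = X - mus
        ll = _mvn_logpdf_grid(E, np.zeros((H, X.shape[1])), st["sg_atoms"])
        logw = np.log(stick_weights(st["v_sg"]) + 1e-300)
        st["c_sg"] = sample_assignments(ll, logw, rng)
        for h in range(H):
            m = st["c_sg"] == h
            if not m.any():
                st["sg_atoms"][h] = self._draw_sigma_atom(rng)
                continue
            Ec = E[m]
            st["sg_atoms"][h] = self._draw_sigma_atom(
                rng, nu=self._nu0 + Ec.shape[0], S=self._S0 + Ec.T @ Ec
            )
        st["v_sg"] = sample_sticks(
            np.bincount(st["c_sg"], minlength=H), self.alpha_sigma, rng
        ).v


class ProductDPMixture(_ProductBase):
    """Independent DPs on the whole mean vector and on the covariance."""

    def _init_state(self, X, rng):
        H = self.trunc
        n, D = X.shape
        k = max(1, min(self.init_clusters, H, n))
        labels = (
            KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31 - 1)))
            .fit_predict(X)
            if k > 1
            else np.zeros(n, dtype=int)
        )
        mu_atoms = np.tile(self._m0, (H, 1))
        for h in range(H):
            m = labels == h
            if m.any():
                mu_atoms[h] = X[m].mean(axis=0)
        st = dict(
            mu_atoms=mu_atoms,
            c_mu=labels.astype(np.int64),
            v_mu=sample_sticks(np.bincount(labels, minlength=H), self.alpha_mu, rng).v,
        )
        self._init_sigma(X, labels, rng, st)
        return st

    def _subject_means(self, st):
        return st["mu_atoms"][st["c_mu"]]

    def _sweep(self, st, X, rng):
        H = self.trunc
        n, D = X.shape
        sigmas = st["sg_atoms"][st["c_sg"]]
        lams = {h: np.linalg.inv(st["sg_atoms"][h]) for h in np.unique(st["c_sg"])}
        # mean-scale assignments: each sample keeps its own Sigma_i
        ll = np.empty((n, H))
        for i in range(n):
            L = linalg.cholesky(sigmas[i], lower=True)
            W = linalg.solve_triangular(
                L, (X[i][None, :] - st["mu_atoms"]).T, lower=True
            )
            ll[i] = -0.5 * np.sum(W * W, axis=0)  # shared constants cancel
        logw = np.log(stick_weights(st["v_mu"]) + 1e-300)
        st["c_mu"] = sample_assignments(ll, logw, rng)
        # mean atoms: normal conjugate with heterogeneous member precisions
        for h in range(H):
            m = np.where(st["c_mu"] == h)[0]
            if m.size == 0:
                st["mu_atoms"][h] = self._m0 + np.sqrt(self._s0) * rng.standard_normal(D)
                continue
            Q = np.diag(1.0 / self._s0)
            b = self._m0 / self._s0
            for i in m:
                Lam = lams[st["c_sg"][i]]
                Q = Q + Lam
                b = b + Lam @ X[i]
            L = linalg.cholesky(Q, lower=True)
            mean = linalg.cho_solve((L, True), b)
            st["mu_atoms"][h] = mean + linalg.solve_triangular(
                L.T, rng.standard_normal(D), lower=False
            )
        st["v_mu"] = sample_sticks(
            np.bincount(st["c_mu"], minlength=H), self.alpha_mu, rng
        ).v
        self._update_sigma_scale(st, X, rng)


class CoordinateProductDPMixture(_ProductBase):
    """Independent DPs on each coordinate of the mean vector."""

    def _init_state(self, X, rng):
        H = self.trunc
        n, D = X.shape
        k = max(1, min(self.init_clusters, H, n))
        labels = np.zeros((n, D), dtype=np.int64)
        mu_atoms = np.tile(self._m0, (H, 1)).T  # D x H scalar atoms
        for dcol in range(D):
            lab = (
                KMeans(
                    n_clusters=k, n_init=3,
                    random_state=int(rng.integers(2**31 - 1)),
                ).fit_predict(X[:, [dcol]])
                if k > 1
                else np.zeros(n, dtype=int)
            )
            labels[:, dcol] = lab
            for h in range(H):
                m = lab == h
                if m.any():
                    mu_atoms[dcol, h] = X[m, dcol].mean()
        v_mu = np.empty((D, H))
        for dcol in range(D):
            v_mu[dcol] = sample_sticks(
                np.bincount(labels[:, dcol], minlength=H), self.alpha_mu, rng
            ).v
        st = dict(mu_atoms=mu_atoms, c_mu=labels, v_mu=v_mu)
        sg_hint = labels[:, 0]
        self._init_sigma(X, sg_hint, rng, st)
        return st

    def _subject_means(self, st):
        n, D = st["c_mu"].shape
        out = np.empty((n, D))
        for dcol in range(D):
            out[:, dcol] = st["mu_atoms"][dcol, st["c_mu"][:, dcol]]
        return out

    def _sweep(self, st, X, rng):
        H = self.trunc
        n, D = X.shape
        lams = {h: np.linalg.inv(st["sg_atoms"][h]) for h in np.unique(st["c_sg"])}
        mus = self._subject_means(st)
        for dcol in range(D):
            # conditional normal of coordinate dcol given the others:
            # loglik(m) = (m - m_old) g_d - 0.5 (m - m_old)^2 Lam_dd
            ll = np.empty((n, H))
            grad = np.empty(n)
            curv = np.empty(n)
            for i in range(n):
                Lam = lams[st["c_sg"][i]]
                r = Lam @ (X[i] - mus[i])
                grad[i] = r[dcol]
                curv[i] = Lam[dcol, dcol]
            delta = st["mu_atoms"][dcol][None, :] - mus[:, dcol][:, None]
            ll = delta * grad[:, None] - 0.5 * delta**2 * curv[:, None]
            logw = np.log(stick_weights(st["v_mu"][dcol]) + 1e-300)
            st["c_mu"][:, dcol] = sample_assignments(ll, logw, rng)
            mus[:, dcol] = st["mu_atoms"][dcol, st["c_mu"][:, dcol]]
            # scalar atom updates
            for h in range(H):
                m = np.where(st["c_mu"][:, dcol] == h)[0]
                if m.size == 0:
                    st["mu_atoms"][dcol, h] = self._m0[dcol] + np.sqrt(
                        self._s0[dcol]
                    ) * rng.standard_normal()
                    continue
                prec = 1.0 / self._s0[dcol]
                b = self._m0[dcol] / self._s0[dcol]
                for i in m:
                    Lam = lams[st["c_sg"][i]]
                    r = Lam @ (X[i] - mus[i])
                    prec += Lam[dcol, dcol]
                    b += r[dcol] + Lam[dcol, dcol] * mus[i, dcol]
                mean = b / prec
                st["mu_atoms"][dcol, h] = mean + rng.standard_normal() / np.sqrt(prec)
                mus[m, dcol] = st["mu_atoms"][dcol, h]
            st["v_mu"][dcol] = sample_sticks(
                np.bincount(st["c_mu"][:, dcol], minlength=H), self.alpha_mu, rng
            ).v
        self._update_sigma_scale(st, X, rng)


def run_dpm_iid(data, hp=None, **kw) -> IidDraws:
    """Fit the standard DP location-scale mixture; returns retained draws."""
    return DPMixture(**_iid_kw(hp, kw)).fit(data).draws_


def run_pdpm_iid(data, hp=None, **kw) -> IidDraws:
    """Fit the product mixture (independent mean / covariance DPs)."""
    return ProductDPMixture(**_iid_kw(hp, kw)).fit(data).draws_


def run_gpdpm_iid(data, hp=None, **kw) -> IidDraws:
    """Fit the coordinate-wise product mixture."""
    return CoordinateProductDPMixture(**_iid_kw(hp, kw)).fit(data).draws_


def _iid_kw(hp, kw):
    out = {}
    if hp is not None:
        out.update(
            trunc=hp.trunc, alpha_mu=hp.alpha_theta, alpha_sigma=hp.alpha_sigma,
            n_iter=hp.n_iter, n_burn=hp.n_burn, thin=hp.thin, random_state=hp.seed,
        )
    out.update(kw)
    return out
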