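"""Posterior draw containers and the single-file archive format.

Archives are NumPy ``.npz`` files with one array per field plus a JSON
metadata entry; layout is documented in the README.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PosteriorDraws", "save_draws", "load_draws"]


@dataclass
class PosteriorDraws:
    """Retained MCMC output of one sampler run.

    Attributes
    ----------
    theta : ndarray (n_draws, n_subjects, D, D*K)
        Subject-level stacked coefficient matrices [A_1 ... A_K] per draw.
    sigma : ndarray (n_draws, n_subjects, D, D)
        Subject-level residual covariances per draw.
    c_theta : ndarray
        Coefficient-scale labels; shape (n_draws, n) for whole-matrix
        clustering, (n_draws, n, D) for row-level, (n_draws, n, K) for
        lag-level clustering.
    c_sigma : ndarray (n_draws, n)
        Covariance-scale labels.
    v_theta, v_sigma : ndarray
        Stick proportions per draw.
    loglik : ndarray (n_draws,)
        Total panel log-likelihood trace.
    """

    theta: np.ndarray
    sigma: np.ndarray
    c_theta: np.ndarray
    c_sigma: np.ndarray
    v_theta: np.ndarray
    v_sigma: np.ndarray
    loglik: np.ndarray
    n_lags: int
    subject_ids: list[str] = field(default_factory=list)
    model: str = ""

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.theta.shape[1]

    @property
    def D(self) -> int:
        return self.theta.shape[2]

    def theta_mean(self) -> np.ndarray:
        """Posterior-mean subject coefficients, (n, D, D*K)."""
        return self.theta.mean(axis=0)

    def sigma_mean(self) -> np.ndarray:
        return self.sigma.mean(axis=0)

    def theta_flat_labels(self) -> np.ndarray:
        """Coefficient-scale labels flattened to (n_draws, units)."""
        return self.c_theta.reshape(self.c_theta.shape[0], -1)


def save_draws(draws: PosteriorDraws, path) -> None:
    meta = json.dumps(
        {"n_lags": draws.n_lags, "subject_ids": draws.subject_ids, "model": draws.model}
    )
    np.savez_compressed(
        path,
        theta=draws.theta,
        sigma=draws.sigma,
        c_theta=draws.c_theta,
        c_sigma=draws.c_sigma,
        v_theta=draws.v_theta,
        v_sigma=draws.v_sigma,
        loglik=draws.loglik,
        meta=np.array(meta),
    )


def load_draws(path) -> PosteriorDraws:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        return PosteriorDraws(
            theta=f["theta"],
            sigma=f["sigma"],
            c_theta=f["c_theta"],
            c_sigma=f["c_sigma"],
            v_theta=f["v_theta"],
            v_sigma=f["v_sigma"],
            loglik=f["loglik"],
            n_lags=int(meta["n_lags"]),
            subject_ids=list(meta["subject_ids"]),
            model=str(meta["model"]),
        )
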