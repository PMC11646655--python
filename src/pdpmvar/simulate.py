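"""Synthetic data: cluster-structured sparse VAR panels and the
independent-data toy example.

Four panel-generation settings differ in how the true coefficient
clusters are laid out:

1. a small number of whole-coefficient-stack clusters;
2. lag-specific clusters (3 for lag 1, 2 for lag 2 by default);
3. row-specific clusters, the number of clusters per target row drawn
   uniformly between 2 and 5;
4. as 3, but each subject's rows are random deviations about the cluster
   mean row (10% of the nonzero-coefficient spread by default).

Residual covariances come in independent clusters drawn inverse-Wishart
with D degrees of freedom and scale (D/2) I.  Nonzero coefficient
positions are chosen to hit the requested sparsity fraction, candidate
draws are rescaled until the companion spectral radius is at most 0.95,
and series are simulated forward exactly as the model's likelihood
assumes: the first max(K, 1) columns are N(0, Sigma) draws and later
columns follow the truncated-lag VAR recursion, with no presample.  A
holdout block (5 columns by default) continues each series for
forecasting evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import PanelTimeSeries, VARCoefficients
from .var import is_stable

__all__ = [
    "SimulationDesign",
    "SimulatedPanel",
    "gen_setting",
    "gen_toy",
    "difference_and_demean",
    "winsorize",
]

_RADIUS_CAP = 0.95
_SETTING4_NOISE = 0.10  # sd of subject deviations, as a fraction of the
                        # nonzero-coefficient sd


@dataclass
class SimulationDesign:
    """Parameters of one simulated panel."""

    setting: int = 1
    n: int = 60
    D: int = 10
    T: int = 200
    K: int = 2
    sparsity: float = 0.75
    n_theta_clusters: tuple[int, ...] | int = 3
    n_sigma_clusters: int = 3
    forecast_holdout: int = 5
    coef_scale: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.setting not in (1, 2, 3, 4):
            raise ValueError("setting must be 1, 2, 3 or 4")
        if not 0.0 < self.sparsity < 1.0:
            raise ValueError("sparsity must lie strictly between 0 and 1")
        if self.n_sigma_clusters < 1 or self.forecast_holdout < 0:
            raise ValueError("cluster counts >= 1 and holdout >= 0 required")
        if self.setting == 2 and isinstance(self.n_theta_clusters, int):
            # default lag-wise cluster counts: 3 for lag 1, 2 for lag 2+
            self.n_theta_clusters = (3,) + (2,) * (self.K - 1)


@dataclass
class SimulatedPanel:
    """A generated panel plus ground truth for evaluation."""

    panel: PanelTimeSeries
    holdout: np.ndarray                 # n x D x holdout
    theta_true: np.ndarray              # n x D x DK (stacked lag matrices)
    sigma_true: np.ndarray              # n x D x D
    theta_labels: np.ndarray            # (n,), (n, K) or (n, D) by setting
    sigma_labels: np.ndarray            # (n,)
    nonzero_mask: np.ndarray            # n x D x DK boolean, True = nonzero
    design: SimulationDesign = None


def _nonzero_values(size: int, scale: float, rng) -> np.ndarray:
    """Signed magnitudes bounded away from zero (uniform in
    [0.5, 1.5] * scale) so the zero/nonzero distinction is well-posed."""
    return rng.choice([-1.0, 1.0], size=size) * rng.uniform(
        0.5 * scale, 1.5 * scale, size=size
    )


def _sparse_matrix(D: int, sparsity: float, scale: float, rng) -> np.ndarray:
    """D x D matrix with floor((1 - sparsity) * D^2) nonzero entries."""
    n_nonzero = int(round((1.0 - sparsity) * D * D))
    if n_nonzero < 1:
        raise ValueError("sparsity leaves no nonzero coefficients")
    A = np.zeros(D * D)
    idx = rng.choice(D * D, size=n_nonzero, replace=False)
    A[idx] = _nonzero_values(n_nonzero, scale, rng)
    return A.reshape(D, D)


def _stabilize(thetas: list[np.ndarray], K: int, cap: float = _RADIUS_CAP) -> float:
    """Rescale a family of stacked coefficient matrices by a common factor
    until every member's companion radius is <= cap.  Mutates in place and
    returns the final maximum radius."""
    for _ in range(200):
        radius = max(
            is_stable(VARCoefficients.from_stacked(A, K))[1] for A in thetas
        )
        if radius <= cap:
            return radius
        shrink = (cap / radius) * 0.98
        for A in thetas:
            A *= shrink
    raise RuntimeError("failed to stabilize coefficient draws")


def _simulate_series(
    A_stacked: np.ndarray, sigma: np.ndarray, T: int, K: int, rng
) -> np.ndarray:
    """Simulate T columns of a VAR(K) from N(0, Sigma) starting values,
    matching the truncated-lag likelihood convention (no presample)."""
    D = sigma.shape[0]
    L = np.linalg.cholesky(sigma)
    X = np.zeros((D, T))
    A = np.stack(np.split(A_stacked, K, axis=1))
    for t in range(T):
        mean = np.zeros(D)
        for k in range(1, min(t, K) + 1):
            mean += A[k - 1] @ X[:, t - k]
        X[:, t] = mean + L @ rng.standard_normal(D)
    return X


def gen_setting(design: SimulationDesign) -> SimulatedPanel:
    """Generate a cluster-structured sparse VAR panel for one setting."""
    d = design
    rng = np.random.default_rng(d.seed)
    D, K, n = d.D, d.K, d.n
    DK = D * K

    # --- residual covariance clusters, independent of the coefficients
    # D degrees of freedom: heavy-tailed (the mean does not exist for
    # df <= D + 1) but draws are SPD with probability 1
    iw = stats.invwishart(df=D, scale=(D / 2.0) * np.eye(D))
    sigma_atoms = np.stack([iw.rvs(random_state=rng) for _ in range(d.n_sigma_clusters)])
    sigma_labels = rng.integers(d.n_sigma_clusters, size=n)
    # guarantee every cluster is hit at least once
    sigma_labels[: d.n_sigma_clusters] = np.arange(d.n_sigma_clusters)

    # --- coefficient clusters per setting
    if d.setting == 1:
        G = int(d.n_theta_clusters)
        atoms = [
            np.concatenate(
                [_sparse_matrix(D, d.sparsity, d.coef_scale, rng) for _ in range(K)],
                axis=1,
            )
            for _ in range(G)
        ]
        _stabilize(atoms, K)
        theta_labels = rng.integers(G, size=n)
        theta_labels[:G] = np.arange(G)
        theta = np.stack([atoms[g] for g in theta_labels])
    elif d.setting == 2:
        counts = tuple(d.n_theta_clusters)
        if len(counts) != K:
            raise ValueError("setting 2 needs one cluster count per lag")
        lag_atoms = [
            [_sparse_matrix(D, d.sparsity, d.coef_scale, rng) for _ in range(c)]
            for c in counts
        ]
        theta_labels = np.stack(
            [rng.integers(c, size=n) for c in counts], axis=1
        )
        for k, c in enumerate(counts):
            theta_labels[:c, k] = np.arange(c)
        theta = np.stack(
            [
                np.concatenate(
                    [lag_atoms[k][theta_labels[i, k]] for k in range(K)], axis=1
                )
                for i in range(n)
            ]
        )
        flat = [theta[i] for i in range(n)]
        _stabilize(flat, K)
        theta = np.stack(flat)
    else:  # settings 3 and 4: row-specific clusters
        row_counts = rng.integers(2, 6, size=D)
        row_atoms = []
        for dd in range(D):
            atoms_d = np.zeros((row_counts[dd], DK))
            n_nonzero = max(1, int(round((1.0 - d.sparsity) * DK)))
            for g in range(row_counts[dd]):
                idx = rng.choice(DK, size=n_nonzero, replace=False)
                atoms_d[g, idx] = _nonzero_values(n_nonzero, d.coef_scale, rng)
            row_atoms.append(atoms_d)
        theta_labels = np.stack(
            [rng.integers(row_counts[dd], size=n) for dd in range(D)], axis=1
        )
        for dd in range(D):
            theta_labels[: row_counts[dd], dd] = np.arange(row_counts[dd])
        theta = np.stack(
            [
                np.stack([row_atoms[dd][theta_labels[i, dd]] for dd in range(D)])
                for i in range(n)
            ]
        )
        if d.setting == 4:
            nz = theta != 0
            noise_sd = _SETTING4_NOISE * (np.std(theta[nz]) if nz.any() else 1.0)
            theta = theta + rng.normal(0.0, noise_sd, size=theta.shape) * nz
        flat = [theta[i] for i in range(n)]
        _stabilize(flat, K)
        theta = np.stack(flat)

    nonzero_mask = theta != 0

    # --- simulate series (T + holdout columns kept per subject)
    subjects = []
    holdout = np.zeros((n, D, d.forecast_holdout))
    sigma_true = sigma_atoms[sigma_labels]
    for i in range(n):
        X = _simulate_series(
            theta[i], sigma_true[i], d.T + d.forecast_holdout, K, rng
        )
        subjects.append((f"s{i:03d}", X[:, : d.T]))
        if d.forecast_holdout:
            holdout[i] = X[:, d.T :]

    return SimulatedPanel(
        panel=PanelTimeSeries(subjects, n_lags=K),
        holdout=holdout,
        theta_true=theta,
        sigma_true=sigma_true,
        theta_labels=theta_labels,
        sigma_labels=sigma_labels,
        nonzero_mask=nonzero_mask,
        design=d,
    )


def gen_toy(
    n: int = 250, D: int = 30, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independent multivariate data with separate mean and covariance
    cluster structures.

    Five mean clusters differ only in the first d = floor(D/3)
    coordinates (pairwise center separation >= 3 within that block,
    identical values elsewhere); five covariance clusters are drawn
    inverse-Wishart, independently of the means.  Returns
    ``(data, mu_labels, sigma_labels)``.
    """
    if D < 6:
        raise ValueError("D must be at least 6")
    if n < 10:
        raise ValueError("n must be at least 10")
    rng = np.random.default_rng(seed)
    d_inf = D // 3
    G = 5

    # centers with pairwise separation >= 3 in the informative block
    for _ in range(500):
        centers = rng.normal(0.0, 3.0, size=(G, d_inf))
        dists = np.linalg.norm(
            centers[:, None, :] - centers[None, :, :], axis=2
        )
        if np.all(dists[np.triu_indices(G, k=1)] >= 3.0):
            break
    else:
        raise RuntimeError("could not place separated cluster centers")
    shared_tail = rng.normal(0.0, 1.0, size=D - d_inf)
    mu_atoms = np.column_stack([centers, np.tile(shared_tail, (G, 1))])

    # covariance clusters must be mutually distinguishable to constitute
    # a partition: each gets its own overall scale (log-spaced) on top of
    # an inverse-Wishart draw, independent of the mean clusters
    scales = np.geomspace(0.5, 4.0, G)
    sigma_atoms = np.stack(
        [
            stats.invwishart(df=D + 2, scale=np.eye(D) * 2.0 * scales[g]).rvs(
                random_state=rng
            )
            for g in range(G)
        ]
    )

    # balanced, independent label draws; every cluster nonempty
    mu_labels = np.tile(np.arange(G), n // G + 1)[:n]
    rng.shuffle(mu_labels)
    sigma_labels = np.tile(np.arange(G), n // G + 1)[:n]
    rng.shuffle(sigma_labels)

    data = np.empty((n, D))
    for i in range(n):
        L = np.linalg.cholesky(sigma_atoms[sigma_labels[i]])
        data[i] = mu_atoms[mu_labels[i]] + L @ rng.standard_normal(D)
    return data, mu_labels, sigma_labels


def difference_and_demean(series: np.ndarray, steps: int = 1) -> np.ndarray:
    """Apply lag-1 differencing ``steps`` times, then remove column means.

    Works on a 1-D series or a T x D matrix (time along axis 0); the
    length shrinks by ``steps``.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x.T).T if squeeze else x
    if x.shape[0] <= steps:
        raise ValueError("series too short for the requested differencing")
    for _ in range(steps):
        x = np.diff(x, axis=0)
    x = x - x.mean(axis=0, keepdims=True)
    return x.ravel() if squeeze else x


def winsorize(series: np.ndarray, n_sd: float = 4.0) -> np.ndarray:
    """Clip values beyond ``n_sd`` robust standard deviations of the
    median (robust SD = 1.4826 * MAD).  A simple outlier guard for raw
    sensor series; not a model component."""
    x = np.asarray(series, dtype=float)
    med = np.median(x, axis=-1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=-1, keepdims=True)
    sd = 1.4826 * np.maximum(mad, 1e-12)
    return np.clip(x, med - n_sd * sd, med + n_sd * sd)
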