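"""Truncated stick-breaking machinery shared by all the mixture samplers.

A truncation level H turns the Dirichlet process into a finite mixture
whose last stick absorbs the leftover mass (v_H = 1), which is the blocked
Gibbs representation: weights pi_h = v_h prod_{l<h} (1 - v_l).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StickState",
    "stick_weights",
    "sample_sticks",
    "sample_assignments",
    "posterior_similarity",
    "similarity_partition",
    "check_truncation",
]

logger = logging.getLogger(__name__)


@dataclass
class StickState:
    """Stick proportions v (length H, v[-1] == 1) and the DP precision."""

    v: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if np.any(self.v <= 0) or np.any(self.v > 1):
            raise ValueError("stick proportions must lie in (0, 1]")
        if self.v[-1] != 1.0:
            raise ValueError("last stick proportion must be 1")
        if self.alpha <= 0:
            raise ValueError("DP precision alpha must be positive")

    @property
    def H(self) -> int:
        return self.v.shape[0]


def stick_weights(state: StickState | np.ndarray) -> np.ndarray:
    """Mixture weights pi_h = v_h prod_{l<h}(1 - v_l); sums to 1 exactly."""
    v = state.v if isinstance(state, StickState) else np.asarray(state, dtype=float)
    with np.errstate(divide="ignore"):
        log1m = (
            np.concatenate([[0.0], np.cumsum(np.log1p(-v[:-1]))])
            if v.shape[0] > 1
            else np.zeros(1)
        )
    pi = v * np.exp(log1m)
    # the final v=1 stick absorbs the remainder so the sum is exactly 1
    pi[-1] = max(0.0, 1.0 - pi[:-1].sum())
    return pi


def sample_sticks(counts: np.ndarray, alpha: float, rng: np.random.Generator) -> StickState:
    """Conjugate stick update: v_h ~ Beta(1 + n_h, alpha + sum_{l>h} n_l)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("occupancy counts must be nonnegative")
    H = counts.shape[0]
    tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
    v = rng.beta(1.0 + counts, alpha + tail)
    v = np.clip(v, 1e-12, 1.0 - 1e-12)
    v[-1] = 1.0
    return StickState(v=v, alpha=alpha)


def sample_assignments(
    log_lik: np.ndarray, log_weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw cluster labels: unit u gets label h with probability
    proportional to exp(log_weights[h] + log_lik[u, h]).

    Computed with max-subtraction for numerical stability.  Labels are
    0-based internally.
    """
    log_lik = np.atleast_2d(np.asarray(log_lik, dtype=float))
    logp = log_lik + np.asarray(log_weights, dtype=float)[None, :]
    m = np.max(logp, axis=1, keepdims=True)
    if np.any(~np.isfinite(m)):
        raise ValueError("a unit has -inf posterior mass in every cluster")
    p = np.exp(logp - m)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(p.shape[0])
    return (np.cumsum(p, axis=1) < u[:, None]).sum(axis=1)


def posterior_similarity(assignment_draws: np.ndarray) -> np.ndarray:
    """Pairwise co-clustering frequency across MCMC draws.

    ``assignment_draws`` has shape (n_draws, n_units); the result is the
    symmetric units x units matrix of the fraction of draws in which two
    units share a label (diagonal exactly 1).  This summary is invariant
    to label switching.
    """
    draws = np.atleast_2d(np.asarray(assignment_draws))
    if draws.shape[0] < 1:
        raise ValueError("need at least one assignment draw")
    n_draws, n_units = draws.shape
    sim = np.zeros((n_units, n_units))
    for row in draws:
        sim += row[:, None] == row[None, :]
    sim /= n_draws
    np.fill_diagonal(sim, 1.0)
    return sim


def similarity_partition(sim: np.ndarray, cut: float = 0.5) -> np.ndarray:
    """Point partition: complete linkage on 1 - similarity, cut at ``cut``."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = sim.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    link = linkage(squareform(dist, checks=False), method="complete")
    return fcluster(link, t=cut, criterion="distance") - 1


def check_truncation(counts: np.ndarray, frac: float = 0.99) -> bool:
    """Warn when the first H-2 clusters hold < ``frac`` of the occupancy
    mass, a sign the truncation level H may be too small."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0 or counts.shape[0] < 3:
        return True
    head = np.sort(counts)[::-1][:-2].sum()
    ok = head >= frac * total
    if not ok:
        logger.warning(
            "truncation level may be too small: top H-2 clusters hold "
            "%.1f%% of occupancy mass", 100.0 * head / total
        )
    return ok
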