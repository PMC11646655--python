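"""Sampler validation by prior / successive-conditional comparison.

The "getting it right" check: the marginal distribution of parameters
along a chain that alternates one Gibbs sweep with a fresh draw of the
data given the parameters must equal the prior.  Comparing moments of
that chain against independent ancestral prior draws, scaled by
autocorrelation-adjusted Monte-Carlo standard errors, detects errors in
any full conditional.
"""

from __future__ import annotations

import numpy as np

from .gibbs import _SubjectStats
from .metrics import effective_sample_size

__all__ = ["geweke_compare"]

_STAT_NAMES = [
    "coef_mean",
    "coef_sq",
    "stick_theta",
    "stick_sigma",
    "inv_psi",
    "inv_xi",
    "loading_mean",
    "loading_sq",
]


def _state_stats(st) -> np.ndarray:
    return np.array(
        [
            st.th_atoms.mean(),
            (st.th_atoms**2).mean(),
            st.v_th.reshape(-1)[0],
            st.v_sg[0],
            (1.0 / st.Psi).mean(),
            (1.0 / st.Xi).mean(),
            st.Gam.mean(),
            (st.Gam**2).mean(),
        ]
    )


def geweke_compare(
    estimator,
    n_subjects: int = 3,
    D: int = 2,
    T: int = 10,
    n_sweeps: int = 5000,
    seed: int = 0,
) -> dict:
    """Run the prior vs successive-conditional comparison for one sampler.

    ``estimator`` is an *unfitted* PDPMVAR / RowPDPMVAR / LagPDPMVAR
    instance whose hyperparameters define the model being validated.
    Returns a dict with per-statistic means, autocorrelation-adjusted
    z-scores, and the worst |z|.
    """
    est = estimator
    est._D, est._n = D, n_subjects
    est._B = min(est.n_factors, D)
    est._hp = est._hyper()
    K = est.n_lags

    rng = np.random.default_rng(seed)
    prior = np.array(
        [_state_stats(est._prior_state(rng)) for _ in range(n_sweeps)]
    )

    rng = np.random.default_rng(seed + 1)
    st = est._prior_state(rng)
    X = est._generate_panel(st, T, rng)
    chain = np.empty_like(prior)
    for it in range(n_sweeps):
        stats_ = [_SubjectStats(Xi, K) for Xi in X]
        est._refresh_sigma_cache(st)
        est._sweep(st, stats_, rng)
        X = est._generate_panel(st, T, rng)
        chain[it] = _state_stats(st)

    out = {"names": list(_STAT_NAMES), "z": [], "prior_mean": [], "chain_mean": []}
    for j in range(prior.shape[1]):
        a, b = prior[:, j], chain[:, j]
        se = np.sqrt(
            a.var() / effective_sample_size(a) + b.var() / effective_sample_size(b)
        )
        z = (a.mean() - b.mean()) / se if se > 0 else 0.0
        out["z"].append(float(z))
        out["prior_mean"].append(float(a.mean()))
        out["chain_mean"].append(float(b.mean()))
    out["max_abs_z"] = float(np.max(np.abs(out["z"])))
    return out
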