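"""Performance metrics: clustering ARI, relative L2 error,
credible-interval feature-selection curves, forecast error, and MCMC
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "adjusted_rand_index",
    "ari_over_draws",
    "relative_l2",
    "selection_curves",
    "forecast_error",
    "effective_sample_size",
    "chain_diagnostics",
    "MetricReport",
]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model-adjusted Rand index between two partitions.

    Equals 1 iff the partitions are identical up to relabeling; 0 is the
    chance level.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.shape[0] < 2:
        raise ValueError("need at least two units")
    return float(adjusted_rand_score(a, b))


def ari_over_draws(assignment_draws: np.ndarray, truth: np.ndarray) -> float:
    """ARI against the true partition, averaged over retained MCMC draws."""
    draws = np.atleast_2d(assignment_draws)
    truth = np.asarray(truth).ravel()
    return float(
        np.mean([adjusted_rand_score(truth, row) for row in draws])
    )


def relative_l2(estimate: np.ndarray, truth: np.ndarray) -> float:
    """||estimate - truth||_F / ||truth||_F."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("estimate and truth must share a shape")
    denom = np.linalg.norm(truth)
    if denom == 0:
        raise ValueError("truth is all-zero; relative error undefined")
    return float(np.linalg.norm(estimate - truth) / denom)


def selection_curves(
    coef_draws: np.ndarray,
    nonzero_mask: np.ndarray,
    n_thresholds: int = 99,
):
    """Credible-interval sweep ROC and precision-recall curves.

    For each threshold q in a grid over (0, 1) a coefficient is called
    nonzero iff its equal-tailed (1 - q) credible interval excludes 0.
    ``coef_draws`` has shape (n_draws, ...); ``nonzero_mask`` flags the
    truly nonzero coefficients and must match the trailing shape.
    Returns ``(auroc, auprc, (fpr, tpr, precision, recall))``; areas by
    the trapezoid rule with (0,0) and (1,1) appended to the ROC curve.
    """
    draws = np.asarray(coef_draws, dtype=float)
    flat = draws.reshape(draws.shape[0], -1)
    truth = np.asarray(nonzero_mask, dtype=bool).ravel()
    if flat.shape[1] != truth.shape[0]:
        raise ValueError("mask shape does not match coefficient draws")
    n_pos = truth.sum()
    if n_pos == 0 or n_pos == truth.shape[0]:
        raise ValueError("degenerate mask: AUROC is undefined")

    qs = np.linspace(0.01, 0.99, n_thresholds)
    tprs, fprs, precs, recs = [], [], [], []
    for q in qs:
        lo = np.quantile(flat, q / 2.0, axis=0)
        hi = np.quantile(flat, 1.0 - q / 2.0, axis=0)
        called = (lo > 0) | (hi < 0)
        tp = np.sum(called & truth)
        fp = np.sum(called & ~truth)
        tprs.append(tp / n_pos)
        fprs.append(fp / (truth.shape[0] - n_pos))
        precs.append(tp / max(called.sum(), 1))
        recs.append(tp / n_pos)

    order = np.argsort(fprs, kind="stable")
    fpr = np.concatenate([[0.0], np.asarray(fprs)[order], [1.0]])
    tpr = np.concatenate([[0.0], np.asarray(tprs)[order], [1.0]])
    tpr = np.maximum.accumulate(tpr)
    auroc = float(np.trapezoid(tpr, fpr))

    order = np.argsort(recs, kind="stable")
    rec = np.asarray(recs)[order]
    prec = np.asarray(precs)[order]
    rec = np.concatenate([[0.0], rec, [1.0]])
    prec = np.concatenate([[prec[0] if prec.size else 1.0], prec, [n_pos / truth.shape[0]]])
    auprc = float(np.trapezoid(prec, rec))
    return auroc, auprc, (fpr, tpr, prec, rec)


def forecast_error(predicted: np.ndarray, actual: np.ndarray):
    """Relative L2 forecast error pooled over subjects, per horizon.

    Both inputs have shape (n_subjects, D, h) (or (D, h) for one
    subject).  Returns ``(per_horizon, cumulative)`` where
    ``per_horizon[j]`` is the pooled Frobenius ratio at horizon j+1 and
    ``cumulative[j]`` pools horizons 1..j+1.
    """
    P = np.asarray(predicted, dtype=float)
    A = np.asarray(actual, dtype=float)
    if P.shape != A.shape:
        raise ValueError("predicted and actual must share a shape")
    if P.ndim == 2:
        P, A = P[None], A[None]
    h = P.shape[2]
    per = np.empty(h)
    cum = np.empty(h)
    for j in range(h):
        num = np.linalg.norm(P[:, :, j] - A[:, :, j])
        den = np.linalg.norm(A[:, :, j])
        per[j] = num / den if den > 0 else np.nan
        numc = np.linalg.norm(P[:, :, : j + 1] - A[:, :, : j + 1])
        denc = np.linalg.norm(A[:, :, : j + 1])
        cum[j] = numc / denc if denc > 0 else np.nan
    return per, cum


def effective_sample_size(trace: np.ndarray) -> float:
    """ESS from the initial-monotone-positive-sequence autocorrelation
    estimator (Geyer-style): n / (1 + 2 sum rho_k)."""
    x = np.asarray(trace, dtype=float).ravel()
    n = x.shape[0]
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = x @ x / n
    if var == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (n * var)
    # sum pairs of consecutive autocorrelations while positive & decreasing
    s = 0.0
    prev = np.inf
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k]
        if pair < 0:
            break
        pair = min(pair, prev)
        s += pair
        prev = pair
    return float(n / (1.0 + 2.0 * s))


@dataclass
class MetricReport:
    """Bundle of evaluation results for one fitted model."""

    ari_theta: float | None = None
    ari_sigma: float | None = None
    rel_l2_theta: float | None = None
    rel_l2_sigma: float | None = None
    auroc: float | None = None
    auprc: float | None = None
    forecast_rel_l2: np.ndarray | None = None
    ess: dict = field(default_factory=dict)
    stationarity_pass: float | None = None

    def to_dict(self) -> dict:
        out = {}
        for k in (
            "ari_theta", "ari_sigma", "rel_l2_theta", "rel_l2_sigma",
            "auroc", "auprc", "stationarity_pass",
        ):
            v = getattr(self, k)
            if v is not None:
                out[k] = float(v)
        if self.forecast_rel_l2 is not None:
            for j, v in enumerate(np.asarray(self.forecast_rel_l2).ravel()):
                out[f"forecast_rel_l2_h{j + 1}"] = float(v)
        out.update({f"ess_{k}": float(v) for k, v in self.ess.items()})
        return out


def chain_diagnostics(traces: dict[str, np.ndarray], alpha: float = 0.05):
    """ESS and augmented Dickey-Fuller stationarity checks per trace.

    A trace passes when the ADF test rejects a unit root at level
    ``alpha``.  Constant traces are reported as inapplicable (None).
    Requires at least 100 retained draws.
    """
    from statsmodels.tsa.stattools import adfuller

    results = {}
    for name, tr in traces.items():
        tr = np.asarray(tr, dtype=float).ravel()
        if tr.shape[0] < 100:
            raise ValueError(f"trace {name!r} too short for diagnostics")
        ess = effective_sample_size(tr)
        if np.ptp(tr) < 1e-12:
            results[name] = {"ess": ess, "adf_pvalue": None, "stationary": None}
            continue
        pval = adfuller(tr, autolag="AIC")[1]
        results[name] = {
            "ess": ess, "adf_pvalue": float(pval), "stationary": bool(pval < alpha)
        }
    return results
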