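"""Domain containers for multi-subject VAR panels.

Coefficient orientation convention, used everywhere in this package:
``A[k][d, j]`` is the effect of variable ``j`` at lag ``k+1`` on variable
``d`` at the current time, i.e. rows index the *target* variable.  In the
effective-connectivity literature these lag matrices are often called
"autocovariance matrices" even though they are regression coefficients,
not covariances of the process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PanelTimeSeries",
    "VARCoefficients",
    "FactorCovariance",
    "SubjectParameters",
    "read_panel_csv",
    "write_panel_csv",
    "build_design",
]


@dataclass
class VARCoefficients:
    """Lag matrices of a VAR(K) process.

    Parameters
    ----------
    A : ndarray of shape (K, D, D)
        ``A[k]`` is the coefficient matrix for lag ``k+1``; rows index the
        target variable, columns the source variable.
    """

    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValueError(
                f"A must have shape (K, D, D); got {self.A.shape}"
            )
        if not np.all(np.isfinite(self.A)):
            raise ValueError("coefficient matrices must be finite")

    @property
    def K(self) -> int:
        return self.A.shape[0]

    @property
    def D(self) -> int:
        return self.A.shape[1]

    def stacked(self) -> np.ndarray:
        """Return the D x (D*K) matrix [A_1 ... A_K]."""
        return np.concatenate(list(self.A), axis=1)

    @classmethod
    def from_stacked(cls, M: np.ndarray, n_lags: int) -> "VARCoefficients":
        M = np.asarray(M, dtype=float)
        D = M.shape[0]
        if M.shape[1] != D * n_lags:
            raise ValueError("stacked matrix has wrong width")
        return cls(np.stack(np.split(M, n_lags, axis=1)))


@dataclass
class FactorCovariance:
    """Low-rank residual covariance Sigma = Gamma diag(Xi) Gamma' + diag(Psi).

    ``Gamma`` (D x B) holds factor loadings under the parameter-expanded
    representation, ``Xi`` (length B) the latent-factor variances, and
    ``Psi`` (length D) the idiosyncratic variances.
    """

    Gamma: np.ndarray
    Xi: np.ndarray
    Psi: np.ndarray

    def __post_init__(self) -> None:
        self.Gamma = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
        self.Xi = np.atleast_1d(np.asarray(self.Xi, dtype=float))
        self.Psi = np.atleast_1d(np.asarray(self.Psi, dtype=float))
        if self.Gamma.shape != (self.D, self.B):
            raise ValueError("Gamma must be D x B")
        if np.any(self.Xi <= 0) or np.any(self.Psi <= 0):
            raise ValueError("Xi and Psi entries must be strictly positive")

    @property
    def D(self) -> int:
        return self.Psi.shape[0]

    @property
    def B(self) -> int:
        return self.Xi.shape[0]


@dataclass
class SubjectParameters:
    """Subject-level VAR parameters (Theta_i, Sigma_i)."""

    theta: VARCoefficients
    sigma: np.ndarray | FactorCovariance

    def sigma_matrix(self) -> np.ndarray:
        from .var import assemble_sigma

        if isinstance(self.sigma, FactorCovariance):
            return assemble_sigma(self.sigma)
        return np.asarray(self.sigma, dtype=float)


@dataclass
class PanelTimeSeries:
    """n subjects' D x T_i observation matrices plus identifiers.

    ``n_lags`` is carried as metadata: the lag order K a model fitted to
    this panel will use.  Every subject must have at least K+1 time points.
    """

    subjects: list[tuple[str, np.ndarray]]
    n_lags: int = 1

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("panel must contain at least one subject")
        cleaned = []
        D = None
        for sid, X in self.subjects:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if not np.all(np.isfinite(X)):
                raise ValueError(f"subject {sid!r} has non-finite values")
            if D is None:
                D = X.shape[0]
            elif X.shape[0] != D:
                raise ValueError("all subjects must share the dimension D")
            if X.shape[1] < self.n_lags + 1:
                raise ValueError(
                    f"subject {sid!r} has T={X.shape[1]} < K+1={self.n_lags + 1}"
                )
            cleaned.append((str(sid), X))
        self.subjects = cleaned

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def D(self) -> int:
        return self.subjects[0][1].shape[0]

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.subjects]

    def matrices(self) -> list[np.ndarray]:
        return [X for _, X in self.subjects]

    def __iter__(self):
        return iter(self.subjects)


def build_design(X: np.ndarray, n_lags: int) -> np.ndarray:
    """Lagged design matrix Z (T x D*K) for a D x T series.

    Row t stacks ``x_{t-1}, ..., x_{t-K}``; entries for unavailable lags
    (t - k < 0) are zero, which encodes the truncated-lag conditional mean
    used by the likelihood (zero mean at t = 0).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D, T = X.shape
    Z = np.zeros((T, D * n_lags))
    for k in range(1, n_lags + 1):
        Z[k:, (k - 1) * D : k * D] = X[:, : T - k].T
    return Z


def write_panel_csv(panel: PanelTimeSeries, path, columns: list[str] | None = None) -> None:
    """Write a panel in long format: subject_id, time_index, value columns."""
    D = panel.D
    if columns is None:
        columns = [f"v{d}" for d in range(D)]
    frames = []
    for sid, X in panel:
        df = pd.DataFrame(X.T, columns=columns)
        df.insert(0, "time_index", np.arange(X.shape[1]))
        df.insert(0, "subject_id", sid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_panel_csv(path, n_lags: int = 1) -> PanelTimeSeries:
    """Read a long-format panel CSV (subject_id, time_index, values...)."""
    df = pd.read_csv(path)
    required = {"subject_id", "time_index"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel CSV must contain columns {sorted(required)}")
    value_cols = [c for c in df.columns if c not in required]
    subjects = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_index")
        t = grp["time_index"].to_numpy()
        if not np.array_equal(t, np.arange(len(t))):
            raise ValueError(
                f"subject {sid!r}: time_index must be 0-based and consecutive"
            )
        subjects.append((str(sid), grp[value_cols].to_numpy().T))
    return PanelTimeSeries(subjects, n_lags=n_lags)
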