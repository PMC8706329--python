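"""PCA fitting, variance-based component choice, and T2/Q outlier tests.

Chemometric quality control: a PCA model of the (log-centered) feature
matrix, with each sample scored by its Hotelling T2 distance inside the
model plane and its Q statistic (squared residual distance to the
model). Control limits at level alpha follow the standard chemometric
formulas — an F-distribution limit for T2 and the Jackson–Mudholkar
approximation (from the residual eigenvalue spectrum) for Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PCAModel:
    """Fitted PCA model.

    ``loadings`` has orthonormal columns (features x A), ``scores`` is
    samples x A, ``eigenvalues`` are the per-component score variances
    (ddof=1), ``explained_variance_ratio`` the per-component fractions
    of total variance, and ``residual_eigenvalues`` the variances of
    the discarded components (used for the Q limit).
    """

    mean: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    residual_eigenvalues: np.ndarray
    n_samples: int
    training_q: np.ndarray | None = None
    sample_index: pd.Index | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.loadings.T + self.mean


@dataclass
class OutlierReport:
    """Per-sample T2 and Q statistics with their alpha-level limits."""

    t2: pd.Series
    q: pd.Series
    t2_limit: float
    q_limit: float
    alpha: float

    @property
    def t2_flag(self) -> pd.Series:
        return self.t2 > self.t2_limit

    @property
    def q_flag(self) -> pd.Series:
        return self.q > self.q_limit

    @property
    def flagged(self) -> pd.Series:
        """Samples outlying on either criterion."""
        return self.t2_flag | self.q_flag


def _effective_rank(s: np.ndarray, n: int, p: int) -> int:
    tol = s.max(initial=0.0) * max(n, p) * np.finfo(float).eps
    return int((s > tol).sum())


def fit_pca(X: np.ndarray | pd.DataFrame, n_components: int) -> PCAModel:
    """Fit PCA by SVD of the column-centered matrix.

    The sign of each loading column is fixed so that its
    largest-magnitude element is positive, making the model
    deterministic. ``n_components`` may not exceed the rank of the
    centered matrix.
    """
    index = X.index if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = _effective_rank(s, n, p)
    if not 1 <= n_components <= rank:
        raise ValueError(f"n_components must be in [1, rank={rank}]")
    eig_all = s**2 / (n - 1)
    total = eig_all.sum()

    loadings = Vt[:n_components].T.copy()
    # sign convention: largest-|.| element of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    loadings *= flip
    scores = Xc @ loadings
    resid = Xc - scores @ loadings.T
    return PCAModel(
        mean=mean,
        loadings=loadings,
        scores=scores,
        eigenvalues=eig_all[:n_components],
        explained_variance_ratio=eig_all[:n_components] / total,
        residual_eigenvalues=eig_all[n_components:rank],
        n_samples=n,
        training_q=(resid**2).sum(axis=1),
        sample_index=index,
    )


def choose_components_by_variance(
    X: np.ndarray | pd.DataFrame, target: float = 0.60
) -> int:
    """Smallest component count reaching the target explained variance."""
    if not 0 < target <= 1:
        raise ValueError("target must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    rank = _effective_rank(s, n, p)
    frac = (s[:rank] ** 2) / (s[:rank] ** 2).sum()
    cum = np.cumsum(frac)
    return int(np.searchsorted(cum, target - 1e-12) + 1)


def _t2_limit(n: int, A: int, alpha: float) -> float:
    return (n - 1) * A / (n - A) * stats.f.ppf(1 - alpha, A, n - A)


def _q_limit(residual_eigenvalues: np.ndarray, alpha: float) -> float:
    """Jackson–Mudholkar approximation of the Q control limit."""
    theta1 = residual_eigenvalues.sum()
    if theta1 <= 0:
        return 0.0
    theta2 = (residual_eigenvalues**2).sum()
    theta3 = (residual_eigenvalues**3).sum()
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2**2)
    if h0 < 1e-3:
        h0 = 1e-3
    z = stats.norm.ppf(1 - alpha)
    inner = (
        z * np.sqrt(2.0 * theta2 * h0**2) / theta1
        + 1.0
        + theta2 * h0 * (h0 - 1.0) / theta1**2
    )
    if inner <= 0:
        return 0.0
    return float(theta1 * inner ** (1.0 / h0))


def outlier_test(
    model: PCAModel, X: np.ndarray | pd.DataFrame | None = None, alpha: float = 0.05
) -> OutlierReport:
    """T2 and Q outlier test at level ``alpha``.

    T2_i = sum_a t_ia^2 / lambda_a against the training-set F limit
    (n-1)A/(n-A) * F(1-alpha; A, n-A); Q_i is the squared residual norm
    against the Jackson–Mudholkar limit. With ``X=None`` the training
    data are tested.
    """
    if X is None:
        scores = model.scores
        q = model.training_q
        index = (
            model.sample_index
            if model.sample_index is not None
            else pd.RangeIndex(scores.shape[0])
        )
    else:
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
        X = np.asarray(X, dtype=float)
        Xc = X - model.mean
        scores = Xc @ model.loadings
        resid = Xc - scores @ model.loadings.T
        q = (resid**2).sum(axis=1)
    n, A = model.n_samples, model.n_components
    if n < A + 1:
        raise ValueError("need more samples than components")
    t2 = (scores**2 / model.eigenvalues[None, :]).sum(axis=1)
    report = OutlierReport(
        t2=pd.Series(t2, index=index),
        q=pd.Series(q, index=index),
        t2_limit=_t2_limit(n, A, alpha),
        q_limit=_q_limit(model.residual_eigenvalues, alpha),
        alpha=alpha,
    )
    return report
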