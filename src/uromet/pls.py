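"""PLS2 for classification: NIPALS, VIP, and stability selection.

Partial least squares regression on a dummy-coded class response
(PLS2C) is the workhorse classifier for wide metabolomics tables
(features >> samples). On top of the fitted model this module provides:

* VIP (variable importance in projection) scores, whose mean square is
  1 by construction, so VIP >= 1 is the conventional relevance cut;
* component-count selection at the first maximum of cross-validated
  MCC;
* stability selection — many sub-models on stratified subsamples, each
  performing iterative VIP-based feature elimination and keeping the
  feature set with the best cross-validated MCC; per-feature selection
  frequencies and out-of-bag majority-vote predictions (MCCoob)
  summarize the ensemble;
* a label-permutation test for the significance of any scalar
  performance statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .validation import (
    CVScheme,
    mcc_from_labels,
    majority_vote,
    repeated_cv_mcc,
    stratified_subsample,
)

_EPS = 1e-12


def dummy_code(y) -> tuple[np.ndarray, np.ndarray]:
    """One-hot dummy matrix (n x n_classes) and the sorted classes."""
    y = np.asarray(y)
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    return Y, classes


@dataclass
class PLSModel:
    """NIPALS PLS2 model.

    ``weights`` (p x A), ``loadings`` (p x A), ``scores`` (n x A),
    ``y_loadings`` (n_resp x A), ``coef`` (p x n_resp). Predictions are
    (X - x_mean) @ coef + y_mean. ``ss_y`` holds the response variance
    captured by each component, the weighting used by VIP.
    """

    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    ss_y: np.ndarray
    classes: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def predict_response(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef + self.y_mean


def fit_pls2(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> PLSModel:
    """Fit PLS2 by NIPALS with X and Y deflation.

    X and Y are centered internally. With a single response column the
    algorithm reduces to PLS1; with ``n_components`` equal to the rank
    of X the fitted values coincide with ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean
    if np.allclose(E, 0):
        raise ValueError("X has zero variance")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    ss_y = np.zeros(n_components)

    for a in range(n_components):
        u = F[:, np.argmax(F.var(axis=0))].copy()
        if np.linalg.norm(u) < _EPS:  # response fully explained
            raise ValueError(f"n_components={n_components} exceeds usable rank (at {a})")
        t_old = None
        for _ in range(max_iter):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw < _EPS:
                raise ValueError(f"n_components={n_components} exceeds usable rank (at {a})")
            w /= nw
            t = E @ w
            tt = t @ t
            if tt < _EPS:
                raise ValueError(f"n_components={n_components} exceeds usable rank (at {a})")
            q = F.T @ t / tt
            if np.linalg.norm(q) < _EPS:
                break
            u = F @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        p_a = E.T @ t / tt
        E = E - np.outer(t, p_a)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, p_a, t, q
        ss_y[a] = tt * (q @ q)

    # B = W (P'W)^{-1} Q'
    R = W @ np.linalg.solve(P.T @ W, np.eye(n_components))
    coef = R @ Q.T
    return PLSModel(
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=Q,
        coef=coef,
        x_mean=x_mean,
        y_mean=y_mean,
        ss_y=ss_y,
    )


def classify(model: PLSModel, X) -> np.ndarray:
    """Two-class decision: the class with the larger dummy prediction.

    Exact ties go to the class with the lower label index.
    """
    if model.classes is None:
        raise ValueError("model carries no class labels; fit via PLSClassifier")
    pred = model.predict_response(X)
    # argmax returns the first (lower-index) maximum: documented tie-break
    return model.classes[np.argmax(pred, axis=1)]


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ) with unit-norm
    weight vectors and SS_a the response variance captured by component
    a. The mean of squared VIPs is 1 (sum VIP_j^2 = p).
    """
    p = model.weights.shape[0]
    w2 = model.weights**2  # columns already unit-norm
    ss = model.ss_y
    if ss.sum() < _EPS:
        return np.ones(p)
    return np.sqrt(p * (w2 @ ss) / ss.sum())


class PLSClassifier:
    """Thin fit/predict wrapper satisfying the harness contract.

    The requested component count is clipped to what the training fold
    can support (min(n_samples - 1, n_features)), so cross-validation
    on very small folds stays well-posed.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components
        self.model_: PLSModel | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Y, classes = dummy_code(y)
        A = min(self.n_components, X.shape[0] - 1, X.shape[1])
        A = max(A, 1)
        while A >= 1:
            try:
                model = fit_pls2(X, Y, A)
                break
            except ValueError:
                A -= 1
                if A == 0:
                    raise
        model.classes = classes
        self.model_ = model
        return self

    def predict(self, X):
        if self.model_ is None:
            raise ValueError("classifier not fitted")
        return classify(self.model_, X)


def select_components(
    X,
    y,
    a_max: int = 5,
    cv_scheme: CVScheme | None = None,
) -> int:
    """Component count at the first maximum of MCCcv.

    Returns the smallest A with MCCcv(A) >= MCCcv(A+1) (ties resolve
    toward the smaller model), or ``a_max`` when MCCcv keeps strictly
    increasing.
    """
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    X = np.asarray(X, dtype=float)
    a_max = min(a_max, X.shape[0] - 1, X.shape[1])
    cv_scheme = cv_scheme or CVScheme()
    mccs = [repeated_cv_mcc(PLSClassifier(1), X, y, cv_scheme)]
    for a in range(1, a_max):
        mccs.append(repeated_cv_mcc(PLSClassifier(a + 1), X, y, cv_scheme))
        if mccs[a - 1] >= mccs[a]:
            return a
    return a_max


@dataclass
class StabilityResult:
    """Aggregate of the stability-selection ensemble."""

    selection_frequency: pd.Series  # per feature, in [0, 1]
    oob_predictions: pd.Series  # majority-vote class per covered sample
    mcc_oob: float
    submodel_mcc_cv: np.ndarray  # best MCCcv of each sub-model
    selected_sets: list[np.ndarray] = field(repr=False, default_factory=list)
    n_components: int = 2
    permutation_p: float | None = None

    def relevant_features(self, threshold: float = 0.5) -> pd.Series:
        """Features selected in at least ``threshold`` of sub-models."""
        keep = self.selection_frequency[self.selection_frequency >= threshold]
        return keep.sort_values(ascending=False)


def _vip_elimination(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    n_components: int,
    inner_scheme: CVScheme,
    vip_threshold: float,
    max_rounds: int,
) -> tuple[np.ndarray, float]:
    """Iterative VIP feature elimination on one training subsample.

    Fit, score by cross-validated MCC, drop features with VIP below the
    threshold, repeat; return the feature set of the best-scoring round
    (earliest round on ties, i.e. the larger feature set).
    """
    active = np.arange(X_tr.shape[1])
    best_feats, best_mcc = active, -np.inf
    for _ in range(max_rounds):
        clf = PLSClassifier(n_components).fit(X_tr[:, active], y_tr)
        m = repeated_cv_mcc(
            PLSClassifier(n_components), X_tr[:, active], y_tr, inner_scheme
        )
        if m > best_mcc:
            best_mcc, best_feats = m, active
        v = vip(clf.model_)
        keep = v >= vip_threshold
        if keep.all() or keep.sum() < 2:
            break
        active = active[keep]
    return best_feats, best_mcc


def stability_selection(
    X,
    y,
    n_sub: int = 200,
    n_components: int | None = None,
    cv_scheme: CVScheme | None = None,
    rng: np.random.Generator | int | None = None,
    subsample: float = 0.8,
    vip_threshold: float = 1.0,
    max_rounds: int = 10,
    feature_ids=None,
) -> StabilityResult:
    """Stability selection around PLS2C.

    For each of ``n_sub`` sub-models: draw a class-stratified random
    subsample (fraction ``subsample``, rest out-of-bag); run iterative
    VIP elimination on the subsample keeping the feature set with the
    best cross-validated MCC; refit on that set and predict the
    out-of-bag samples. Aggregation: per-feature selection frequency
    over sub-models, and each sample's out-of-bag class by majority
    vote, summarized as MCCoob. Fully reproducible under a fixed rng.

    ``n_components=None`` selects the count once on the full data at
    the first MCCcv maximum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("both classes need at least 2 members")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cv_scheme = cv_scheme or CVScheme(repeats=1, folds=5)
    if n_components is None:
        n_components = select_components(
            X, y, a_max=5, cv_scheme=CVScheme(cv_scheme.repeats, cv_scheme.folds, 0)
        )

    n, p = X.shape
    sel_counts = np.zeros(p)
    votes: dict[int, list] = {i: [] for i in range(n)}
    sub_mccs = np.zeros(n_sub)
    sets: list[np.ndarray] = []
    for b in range(n_sub):
        train_idx = stratified_subsample(y, subsample, rng)
        oob = np.setdiff1d(np.arange(n), train_idx)
        inner = CVScheme(cv_scheme.repeats, cv_scheme.folds, int(rng.integers(2**31 - 1)))
        feats, best_mcc = _vip_elimination(
            X[train_idx], y[train_idx], n_components, inner, vip_threshold, max_rounds
        )
        sel_counts[feats] += 1
        sub_mccs[b] = best_mcc
        sets.append(feats)
        clf = PLSClassifier(n_components).fit(X[np.ix_(train_idx, feats)], y[train_idx])
        for i, pred in zip(oob, clf.predict(X[np.ix_(oob, feats)])):
            votes[int(i)].append(pred)

    covered = [i for i in range(n) if votes[i]]
    agg = np.array([majority_vote(votes[i], classes) for i in covered])
    mcc_oob = mcc_from_labels(y[covered], agg)
    ids = pd.Index(feature_ids) if feature_ids is not None else pd.RangeIndex(p)
    oob_pred = pd.Series(agg, index=[ids_i for ids_i in covered])
    return StabilityResult(
        selection_frequency=pd.Series(sel_counts / n_sub, index=ids),
        oob_predictions=oob_pred,
        mcc_oob=mcc_oob,
        submodel_mcc_cv=sub_mccs,
        selected_sets=sets,
        n_components=n_components,
    )


def permutation_test(
    analysis_fn: Callable[[np.ndarray, np.ndarray], float],
    X,
    y,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation significance of a performance statistic.

    ``analysis_fn(X, y)`` must return a scalar (e.g. MCCcv or MCCoob).
    Only the labels are permuted; p uses the add-one convention
    p = (1 + #{permuted >= observed}) / (n_perm + 1).

    Returns (p, observed statistic, permuted statistics).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    observed = float(analysis_fn(X, y))
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm_stats[i] = analysis_fn(X, rng.permutation(y))
    p = (1.0 + np.sum(perm_stats >= observed)) / (n_perm + 1.0)
    return float(p), observed, perm_stats
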