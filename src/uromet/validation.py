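"""Classifier-agnostic evaluation: MCC, repeated k-fold CV, out-of-bag.

Every classifier in the pipeline — PLS2 for classification, random
forest, or anything exposing ``fit(X, y)`` / ``predict(X)`` — is scored
through the same code paths: the Matthews correlation coefficient
(MCC), its 50-repeated 5-fold cross-validated estimate (MCCcv), and
its out-of-bag ensemble estimate (MCCoob). Folds are stratified: with
classes as small as 11 vs 13, unstratified splits frequently leave a
fold without one class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold


@runtime_checkable
class BaseClassifier(Protocol):
    """Minimal learner contract accepted by the harness."""

    def fit(self, X, y): ...

    def predict(self, X): ...


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class CVScheme:
    """Repeated stratified k-fold specification."""

    repeats: int = 50
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a margin is empty.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), the balanced
    binary performance measure in [-1, 1]; the zero convention for a
    degenerate margin prevents NaN propagation.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def mcc_from_labels(y_true, y_pred, positive=None) -> float:
    """MCC of two binary label vectors (labels need not be 0/1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if len(classes) > 2:
        raise ValueError("binary labels required")
    pos = classes[-1] if positive is None else positive
    t = y_true == pos
    p = y_pred == pos
    return mcc(
        ConfusionCounts(
            tp=int((t & p).sum()),
            tn=int((~t & ~p).sum()),
            fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()),
        )
    )


def repeated_cv_mcc(
    learner: BaseClassifier,
    X: np.ndarray,
    y: np.ndarray,
    scheme: CVScheme | None = None,
) -> float:
    """MCCcv: mean over repeats of the pooled-fold MCC.

    Each repeat draws a fresh stratified fold split; out-of-fold
    predictions are pooled within the repeat, one MCC computed per
    repeat, then averaged. Pooling first stabilizes the fold-level MCC
    at small n.
    """
    scheme = scheme or CVScheme()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < scheme.folds:
        raise ValueError("smallest class has fewer members than folds")
    rng = np.random.default_rng(scheme.seed)
    per_repeat = []
    for _ in range(scheme.repeats):
        splitter = StratifiedKFold(
            n_splits=scheme.folds,
            shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        pred = np.empty(len(y), dtype=y.dtype)
        for train, test in splitter.split(X, y):
            learner.fit(X[train], y[train])
            pred[test] = learner.predict(X[test])
        per_repeat.append(mcc_from_labels(y, pred))
    return float(np.mean(per_repeat))


def oob_mcc(
    learner_factory: Callable[[], BaseClassifier],
    X: np.ndarray,
    y: np.ndarray,
    n_models: int = 200,
    rng: np.random.Generator | int | None = None,
    subsample: float = 0.8,
) -> float:
    """MCCoob of an ensemble of resampled models.

    Each model trains on a class-stratified subsample (fraction
    ``subsample``, without replacement); each sample's prediction is
    the majority vote over the models where it was out-of-bag. Samples
    never out-of-bag are excluded with a warning.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    votes: dict[int, list] = {i: [] for i in range(len(y))}
    for _ in range(n_models):
        train_idx = stratified_subsample(y, subsample, rng)
        oob = np.setdiff1d(np.arange(len(y)), train_idx)
        learner = learner_factory()
        learner.fit(X[train_idx], y[train_idx])
        if len(oob):
            for i, p in zip(oob, learner.predict(X[oob])):
                votes[int(i)].append(p)
    covered = [i for i in range(len(y)) if votes[i]]
    if len(covered) < len(y):
        warnings.warn(
            f"{len(y) - len(covered)} samples never out-of-bag; excluded from MCCoob",
            stacklevel=2,
        )
    if not covered:
        raise ValueError("no sample was ever out-of-bag")
    agg = np.array([majority_vote(votes[i], classes) for i in covered])
    return mcc_from_labels(y[covered], agg)


def stratified_subsample(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a class-stratified subsample without replacement."""
    idx = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        k = max(1, int(round(fraction * len(members))))
        if k >= len(members):
            k = len(members) - 1  # always leave at least one OOB per class
        if k < 1:
            raise ValueError("class too small to subsample")
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def majority_vote(labels: list, classes: np.ndarray):
    """Most frequent label; ties resolve to the lower class index."""
    counts = {c: 0 for c in classes}
    for v in labels:
        counts[v] += 1
    best = max(counts.values())
    for c in classes:  # class order gives the documented tie-break
        if counts[c] == best:
            return c


def random_forest_factory(
    seed: int = 0, n_estimators: int = 500
) -> Callable[[], BaseClassifier]:
    """Conventional random forest (500 trees, sqrt(p) features/split)."""

    def make() -> BaseClassifier:
        return RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )

    return make
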