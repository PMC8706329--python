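"""Feature-filtering cascade, imputation, PQN normalization and scaling.

The preprocessing applied to an untargeted feature table before any
statistics, in a fixed order:

1. drop features with any missing value among the QC injections;
2. drop features with P95(Blank) / P5(QC) above a contamination
   threshold (default 0.20);
3. drop features whose QC coefficient of variation exceeds 20%;
4. impute remaining missing values uniformly on (0, feature minimum) —
   missingness in these data is left-censoring-like, so a random draw
   below the observed minimum is the least-assumption fill;
5. probabilistic quotient normalization (PQN) against the feature-wise
   median of the QC samples, removing per-sample dilution;
6. re-apply the QC CV filter on normalized data;
7. natural-log transform and mean-center (for multivariate modelling).

Filters only ever drop columns; retained intensity values are never
altered by a filter. Percentiles use linear interpolation of order
statistics and CVs use the sample (n-1) standard deviation, so every
keep/drop decision is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureTable


@dataclass
class FilterReport:
    """Per-rule feature-removal counts, in application order."""

    initial: int
    steps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def surviving(self) -> int:
        return self.initial - sum(n for _, n in self.steps)

    def add(self, rule: str, removed: int) -> None:
        self.steps.append((rule, int(removed)))

    def merged_with(self, other: "FilterReport") -> "FilterReport":
        if other.initial != self.surviving:
            raise ValueError("filter reports do not telescope")
        return FilterReport(self.initial, self.steps + other.steps)

    def to_frame(self) -> pd.DataFrame:
        rows = [("initial", 0, self.initial)]
        remaining = self.initial
        for rule, n in self.steps:
            remaining -= n
            rows.append((rule, n, remaining))
        return pd.DataFrame(rows, columns=["rule", "removed", "surviving"])


def filter_missing_in_qc(table: FeatureTable) -> tuple[FeatureTable, FilterReport]:
    """Drop every feature with at least one missing value in the QCs."""
    qc = table.qc
    if qc.shape[0] == 0:
        raise ValueError("no QC rows in table")
    keep = qc.notna().all(axis=0)
    report = FilterReport(table.n_features)
    report.add("missing_in_qc", int((~keep).sum()))
    return table.select_features(keep.index[keep]), report


def filter_blank_ratio(
    table: FeatureTable, threshold: float = 0.20
) -> tuple[FeatureTable, FilterReport]:
    """Drop features with P95(Blank) / P5(QC) above ``threshold``.

    Missing blank values are treated as zero signal. Features whose QC
    5th percentile is not positive cannot pass the test and are
    removed.
    """
    if table.blank.shape[0] == 0:
        raise ValueError("no Blank rows in table")
    if table.qc.shape[0] == 0:
        raise ValueError("no QC rows in table")
    blank = table.blank.fillna(0.0).to_numpy()
    qc = table.qc.to_numpy()
    p95_blank = np.percentile(blank, 95, axis=0)  # linear interpolation
    p5_qc = np.nanpercentile(qc, 5, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p5_qc > 0, p95_blank / p5_qc, np.inf)
    keep = ratio <= threshold
    report = FilterReport(table.n_features)
    report.add("blank_ratio", int((~keep).sum()))
    return table.select_features(np.asarray(table.feature_ids)[keep]), report


def filter_qc_cv(
    table: FeatureTable, max_cv: float = 0.20, rule_name: str = "qc_cv"
) -> tuple[FeatureTable, FilterReport]:
    """Drop features whose QC coefficient of variation exceeds ``max_cv``.

    CV = sample (ddof=1) SD / mean over the QC rows, missing values
    ignored. Idempotent, and re-applicable after normalization.
    """
    qc = table.qc
    if qc.shape[0] < 2:
        raise ValueError("need at least 2 QC rows to compute a CV")
    mean = qc.mean(axis=0, skipna=True)
    sd = qc.std(axis=0, ddof=1, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    keep = cv.fillna(np.inf) <= max_cv
    keep &= mean > 0
    report = FilterReport(table.n_features)
    report.add(rule_name, int((~keep).sum()))
    return table.select_features(keep.index[keep]), report


def impute_missing(
    table: FeatureTable, rng: np.random.Generator | int | None = None
) -> FeatureTable:
    """Fill each missing entry with a uniform draw on (0, feature min).

    The feature minimum is its smallest observed value anywhere in the
    table; observed entries are untouched. A feature with no observed
    value at all is an error.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = table.intensities.to_numpy(dtype=float).copy()
    missing = np.isnan(x)
    if not missing.any():
        return table.copy()
    if np.all(missing, axis=0).any():
        bad = np.asarray(table.feature_ids)[np.all(missing, axis=0)]
        raise ValueError(f"features entirely missing: {list(bad[:5])} ...")
    fmin = np.nanmin(x, axis=0)
    draws = rng.uniform(0.0, 1.0, size=x.shape) * fmin[None, :]
    # open interval (0, min): resample the measure-zero endpoints away
    draws = np.where(draws == 0.0, fmin[None, :] * 0.5, draws)
    x[missing] = draws[missing]
    out = table.copy()
    out.intensities.iloc[:, :] = x
    return out


def pqn_normalize(
    table: FeatureTable, reference: str = "qc"
) -> tuple[FeatureTable, pd.Series]:
    """Probabilistic quotient normalization.

    Each sample is divided by the median over features of its quotients
    to a reference spectrum, removing multiplicative dilution. The
    reference is the feature-wise median of the QC samples (the pooled,
    stable injections) or, with ``reference="study"``, of the Study
    samples. Returns the normalized table and the per-sample quotients
    for audit.
    """
    x = table.intensities
    if x.isna().any().any():
        raise ValueError("PQN requires a complete (imputed) table")
    if reference == "qc":
        ref = table.qc.median(axis=0)
    elif reference == "study":
        ref = table.study.median(axis=0)
    else:
        raise ValueError("reference must be 'qc' or 'study'")
    ok = ref > 0
    if not ok.any():
        raise ValueError("PQN reference is zero for all features")
    quotients = (x.loc[:, ok] / ref[ok]).median(axis=1)
    out = table.copy()
    out.intensities = x.div(quotients, axis=0)
    return out, quotients


def log_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform then column mean-centering.

    Input must be strictly positive. Output column means are zero to
    numerical precision; this is the model-ready matrix for PCA/PLS.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("log_center requires a complete matrix")
    if (vals <= 0).any():
        raise ValueError("log_center requires strictly positive intensities")
    logged = np.log(vals)
    centered = logged - logged.mean(axis=0, keepdims=True)
    return pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)


def preprocess(
    table: FeatureTable,
    blank_threshold: float = 0.20,
    max_cv: float = 0.20,
    seed: int | None = 0,
    pqn_reference: str = "qc",
) -> tuple[FeatureTable, pd.Series, FilterReport]:
    """Run the full cascade (filters, imputation, PQN, CV re-filter).

    Returns the normalized feature table (still on the intensity scale,
    ready for ``log_center`` or univariate statistics), the PQN
    quotients, and the telescoping filter report.
    """
    t, report = filter_missing_in_qc(table)
    t, r2 = filter_blank_ratio(t, threshold=blank_threshold)
    report = report.merged_with(r2)
    t, r3 = filter_qc_cv(t, max_cv=max_cv)
    report = report.merged_with(r3)
    t = impute_missing(t, np.random.default_rng(seed))
    t, quotients = pqn_normalize(t, reference=pqn_reference)
    t, r4 = filter_qc_cv(t, max_cv=max_cv, rule_name="qc_cv_post_norm")
    report = report.merged_with(r4)
    return t, quotients, report
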