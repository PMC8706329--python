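"""Per-feature two-group screening: fold change, Mann-Whitney, Storey q.

Each feature is tested for a location difference between two groups of
study samples with the Mann-Whitney U test, its effect size expressed
as the log2 ratio of group medians (computed on normalized, un-logged
intensities), and the family of p-values corrected for multiple
testing with Storey's q-value, which estimates the null proportion pi0
instead of assuming it is 1. The result is a volcano-ready table with
the conventional significance flags |log2FC| >= 1 and pMW <= 0.05.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable


def fold_change(group_a, group_b) -> tuple[float, float]:
    """(FC, log2FC) with FC = median(A) / median(B)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mb = np.median(b)
    if mb == 0:
        raise ValueError("zero median in denominator group")
    fc = float(np.median(a) / mb)
    return fc, float(np.log2(fc))


def mann_whitney(xs, ys) -> tuple[float, float]:
    """Mann-Whitney U (of ``xs``) and two-sided p.

    Exact enumeration when n1 + n2 <= 20 with no ties, the
    tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xs, ys])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def storey_pi0(pvals, lambdas=None) -> float:
    """Estimate the null proportion pi0 by the lambda smoother.

    Raw estimates pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over
    the grid 0.05, 0.10, ..., 0.95 are smoothed with a least-squares
    cubic and evaluated at the largest lambda; the result is clipped to
    (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    raw = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, raw, 3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    q_i = pi0 * min_{j: p_j >= p_i} (m p_j / rank_j); with pi0 = 1 this
    reduces exactly to Benjamini-Hochberg adjusted p-values. Monotone
    non-decreasing in p, clipped to (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def volcano_table(
    table: FeatureTable,
    groups: tuple[str, str] | None = None,
    p_limit: float = 0.05,
    fc_limit: float = 1.0,
) -> pd.DataFrame:
    """Volcano table: log2FC, pMW and q per feature, with flags.

    ``groups`` names (numerator, denominator) classes; defaults to the
    sorted pair present among the study samples. Intensities are
    expected normalized but un-logged. Flags mark |log2FC| >=
    ``fc_limit`` and pMW <= ``p_limit``.
    """
    study = table.study
    labels = table.study_labels
    present = sorted(labels.dropna().unique())
    if groups is None:
        if len(present) != 2:
            raise ValueError(f"expected exactly two classes, found {present}")
        groups = (present[0], present[1])
    ga, gb = groups
    A = study.loc[labels == ga]
    B = study.loc[labels == gb]
    if len(A) < 2 or len(B) < 2:
        raise ValueError("need at least 2 samples per group")

    rows = []
    for fid in table.feature_ids:
        a, b = A[fid].to_numpy(), B[fid].to_numpy()
        fc, lfc = fold_change(a, b)
        _, p = mann_whitney(a, b)
        rows.append((fid, float(np.median(a)), float(np.median(b)), fc, lfc, p))
    out = pd.DataFrame(
        rows,
        columns=["feature", "median_a", "median_b", "fc", "log2fc", "p_mw"],
    ).set_index("feature")
    out["qvalue"] = storey_qvalues(out["p_mw"].to_numpy())
    out["flag_fc"] = out["log2fc"].abs() >= fc_limit
    out["flag_p"] = out["p_mw"] <= p_limit
    return out


def export_volcano(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
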