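"""Cohort-metadata screening.

Categorical risk factors (binary exposures such as smoke exposure or
atopic parents) are compared between outcome groups with Fisher's
exact test; continuous variables are dispatched by a Shapiro-Wilk
normality gate (both groups p > 0.10) to either a t-test or a
Mann-Whitney test. The two-sided Fisher p follows the
point-probability convention (sum of hypergeometric probabilities of
tables no more likely than the observed one) — the convention of R's
``fisher.test``, which makes the printed cohort-table values exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContingencyTable2x2:
    """Counts a, b / c, d: rows = groups, columns = factor yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(table: ContingencyTable2x2 | np.ndarray | list) -> float:
    """Two-sided Fisher exact p (point-probability method)."""
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("2x2 table required")
    if arr.min() < 0:
        raise ValueError("cell counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def continuous_test(
    xs, ys, normality_alpha: float = 0.10, equal_var: bool = False
) -> tuple[str, float]:
    """Shapiro-Wilk-gated two-group test.

    Both groups normal at the gate (Shapiro-Wilk p > ``normality_alpha``
    in each) -> t-test (Welch by default); otherwise Mann-Whitney.
    Returns (test name, two-sided p).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3 or len(ys) < 3:
        raise ValueError("need n >= 3 per group for the normality gate")
    if np.ptp(xs) == 0 and np.ptp(ys) == 0 and xs[0] == ys[0]:
        return ("t-test", 1.0)  # all values identical: no evidence either way
    px = stats.shapiro(xs).pvalue if np.ptp(xs) > 0 else 0.0
    py = stats.shapiro(ys).pvalue if np.ptp(ys) > 0 else 0.0
    if px > normality_alpha and py > normality_alpha:
        return ("t-test", float(stats.ttest_ind(xs, ys, equal_var=equal_var).pvalue))
    return ("mann-whitney", float(stats.mannwhitneyu(xs, ys, alternative="two-sided").pvalue))


def screen_metadata(
    metadata: pd.DataFrame,
    outcome: str | pd.Series,
    categorical: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-factor association screen against a binary outcome.

    Binary/categorical factors get Fisher's exact test with per-group
    counts and percentages (cohort-table layout); continuous factors go
    through the normality-gated dispatch. Factors are typed
    automatically (<= 2 distinct non-null values -> categorical) unless
    listed explicitly.
    """
    if isinstance(outcome, str):
        y = metadata[outcome]
        factors = [c for c in metadata.columns if c != outcome]
    else:
        y = outcome
        factors = list(metadata.columns)
    groups = sorted(pd.Series(y).dropna().unique())
    if len(groups) != 2:
        raise ValueError("outcome must be binary")
    g1 = metadata.loc[y == groups[0]]
    g2 = metadata.loc[y == groups[1]]

    rows = []
    for f in factors:
        col = metadata[f]
        is_cat = (
            f in categorical
            if categorical is not None
            else (col.nunique(dropna=True) <= 2 or not pd.api.types.is_numeric_dtype(col))
        )
        if is_cat:
            levels = sorted(col.dropna().unique())
            pos = levels[-1]  # "factor present" = higher level (1 for 0/1)
            a = int((g1[f] == pos).sum())
            b = int((g1[f] != pos).sum())
            c = int((g2[f] == pos).sum())
            d = int((g2[f] != pos).sum())
            p = fisher_exact(ContingencyTable2x2(a, b, c, d))
            rows.append(
                {
                    "factor": f,
                    "test": "fisher",
                    f"n_{groups[0]}": a,
                    f"pct_{groups[0]}": 100 * a / max(a + b, 1),
                    f"n_{groups[1]}": c,
                    f"pct_{groups[1]}": 100 * c / max(c + d, 1),
                    "p": p,
                    "significant": p <= alpha,
                }
            )
        else:
            name, p = continuous_test(g1[f].dropna(), g2[f].dropna())
            rows.append(
                {
                    "factor": f,
                    "test": name,
                    f"n_{groups[0]}": int(g1[f].notna().sum()),
                    f"pct_{groups[0]}": np.nan,
                    f"n_{groups[1]}": int(g2[f].notna().sum()),
                    f"pct_{groups[1]}": np.nan,
                    "p": p,
                    "significant": p <= alpha,
                }
            )
    return pd.DataFrame(rows).set_index("factor")
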