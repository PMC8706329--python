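"""Sample-by-feature intensity table with sample roles and class labels.

The central container of the package: an untargeted LC-MS feature table
whose rows are injections (Study samples, pooled QC samples, solvent
Blanks) and whose columns are Rt_mass features ("1.23_180.0634" style,
retention time + m/z). Missing intensities are NaN; the missing mask is
implicit in the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROLES = ("Study", "QC", "Blank")


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with per-sample metadata.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Non-negative intensities, one row per injection, one column per
        Rt_mass feature. ``NaN`` marks a missing value.
    roles : pandas.Series
        Per-sample role, one of ``"Study"``, ``"QC"``, ``"Blank"``;
        index-aligned with ``intensities``.
    class_labels : pandas.Series
        Optional per-sample class label; expected for Study samples,
        ``NaN`` elsewhere.
    """

    intensities: pd.DataFrame
    roles: pd.Series
    class_labels: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.class_labels is None:
            self.class_labels = pd.Series(
                [np.nan] * len(self.intensities), index=self.intensities.index
            )
        if not self.intensities.index.equals(self.roles.index):
            raise ValueError("roles index must match intensities index")
        if not self.intensities.index.equals(self.class_labels.index):
            raise ValueError("class_labels index must match intensities index")
        bad = set(self.roles.unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        if self.intensities.columns.duplicated().any():
            raise ValueError("feature ids must be unique")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative where present")

    # ---- basic views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def rows(self, role: str) -> pd.DataFrame:
        """Intensity sub-matrix for one sample role."""
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return self.intensities.loc[self.roles == role]

    @property
    def study(self) -> pd.DataFrame:
        return self.rows("Study")

    @property
    def qc(self) -> pd.DataFrame:
        return self.rows("QC")

    @property
    def blank(self) -> pd.DataFrame:
        return self.rows("Blank")

    @property
    def study_labels(self) -> pd.Series:
        return self.class_labels.loc[self.roles == "Study"]

    # ---- subsetting --------------------------------------------------

    def select_features(self, keep: pd.Index | list[str] | np.ndarray) -> "FeatureTable":
        """Column subset; intensity values are never altered."""
        return FeatureTable(
            self.intensities.loc[:, list(keep)].copy(),
            self.roles.copy(),
            self.class_labels.copy(),
        )

    def select_samples(self, keep_index) -> "FeatureTable":
        return FeatureTable(
            self.intensities.loc[keep_index].copy(),
            self.roles.loc[keep_index].copy(),
            self.class_labels.loc[keep_index].copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.roles.copy(), self.class_labels.copy()
        )

    # ---- I/O ---------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the documented TSV dialect.

        Columns: ``sample_id``, ``role``, ``class_label`` (``NA`` when
        absent), then one column per feature. Missing intensities are
        empty cells.
        """
        out = pd.DataFrame(index=self.intensities.index)
        out["sample_id"] = self.intensities.index
        out["role"] = self.roles
        out["class_label"] = self.class_labels
        out = pd.concat([out, self.intensities], axis=1)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        required = ["sample_id", "role", "class_label"]
        if list(df.columns[:3]) != required:
            raise ValueError(f"feature table must start with columns {required}")
        df = df.set_index("sample_id")
        df.index.name = None
        roles = df["role"]
        labels = df["class_label"]
        intensities = df.drop(columns=["role", "class_label"]).astype(float)
        return cls(intensities, roles, labels)
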