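"""End-to-end two-group comparison: the full study workflow from config.

Stages run in a fixed order, each seeded from the study seed:

    preprocess -> PCA outlier gate (alpha = 0.05) -> onion D-optimal
    balancing of the majority class -> PLS2C stability selection and a
    random-forest harness with permutation tests -> univariate
    screening with Storey FDR -> report.

Every stage output is a pure function of (inputs, config, seed); the
report serializes to JSON plus TSV tables so re-runs are comparable
byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import FeatureTable
from .synthetic import SimConfig, generate_cohort
from .preprocessing import preprocess, log_center
from .pca_qc import fit_pca, choose_components_by_variance, outlier_test
from .onion import CandidateSet, onion_select
from .pls import PLSClassifier, stability_selection, permutation_test
from .validation import CVScheme, oob_mcc, repeated_cv_mcc, random_forest_factory


@dataclass
class StudyConfig:
    """Everything a comparison run needs.

    Either ``table_path`` (TSV in the documented dialect) or ``sim``
    (a synthetic-cohort config) supplies the data. ``design_k`` of
    ``None`` balances to ceil(1.2 x minority class size).
    """

    table_path: str | None = None
    sim: SimConfig | None = None
    groups: tuple[str, str] | None = None
    blank_threshold: float = 0.20
    max_cv: float = 0.20
    variance_target: float = 0.60
    alpha: float = 0.05
    design_k: int | None = None
    n_layers: int = 3
    cv_repeats: int = 10
    cv_folds: int = 5
    n_sub: int = 200
    n_perm: int = 199
    n_components: int | None = None
    rf_trees: int = 500
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("blank_threshold", "max_cv", "variance_target"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("cv_repeats", "cv_folds", "n_sub", "n_perm", "rf_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.table_path is None and self.sim is None:
            raise ValueError("provide table_path or sim")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if "dilution_range" in sim:
                sim["dilution_range"] = tuple(sim["dilution_range"])
            d["sim"] = SimConfig(**sim)
        if "groups" in d and d["groups"] is not None:
            d["groups"] = tuple(d["groups"])
        return cls(**d)


@dataclass
class ComparisonReport:
    """Serializable record of one comparison run."""

    filter_report: pd.DataFrame
    outliers: list
    n_components_pca: int
    selected_majority: list
    mcc_oob_pls: float
    perm_p_pls: float
    mcc_oob_rf: float
    perm_p_rf: float
    n_components_pls: int
    relevant_features: pd.Series
    selection_frequency: pd.Series
    volcano: pd.DataFrame
    seed: int

    def summary(self) -> dict:
        return {
            "n_features_surviving": int(self.filter_report["surviving"].iloc[-1]),
            "outliers_excluded": list(map(str, self.outliers)),
            "pca_components": int(self.n_components_pca),
            "selected_majority_subset": list(map(str, self.selected_majority)),
            "pls2c": {
                "n_components": int(self.n_components_pls),
                "mcc_oob": round(float(self.mcc_oob_pls), 4),
                "permutation_p": round(float(self.perm_p_pls), 6),
            },
            "random_forest": {
                "mcc_oob": round(float(self.mcc_oob_rf), 4),
                "permutation_p": round(float(self.perm_p_rf), 6),
            },
            "relevant_features": {
                str(k): round(float(v), 4) for k, v in self.relevant_features.items()
            },
            "n_significant_q10": int((self.volcano["qvalue"] < 0.10).sum()),
            "min_qvalue": float(self.volcano["qvalue"].min()),
            "seed": int(self.seed),
        }

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.summary(), indent=1, sort_keys=True))
        self.filter_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
        self.volcano.to_csv(out / "volcano.tsv", sep="\t")
        self.selection_frequency.rename("selection_frequency").to_csv(
            out / "selection_frequency.tsv", sep="\t"
        )


def run_comparison(config: StudyConfig) -> ComparisonReport:
    """Execute the full comparison pipeline; see module docstring."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(6)]

    if config.table_path is not None:
        table = FeatureTable.from_tsv(config.table_path)
    else:
        table, _ = generate_cohort(config.sim)

    # 1. preprocessing cascade
    norm, _, report = preprocess(
        table,
        blank_threshold=config.blank_threshold,
        max_cv=config.max_cv,
        seed=seeds[0],
    )

    # 2. PCA outlier gate on the study samples
    X_study = log_center(norm.study)
    A = choose_components_by_variance(X_study, config.variance_target)
    pca = fit_pca(X_study, A)
    out_rep = outlier_test(pca, X_study, alpha=config.alpha)
    outliers = list(out_rep.flagged.index[out_rep.flagged])
    kept = [i for i in norm.study.index if i not in set(outliers)]

    labels = norm.study_labels.loc[kept]
    groups = config.groups or tuple(sorted(labels.dropna().unique()))
    if len(groups) != 2:
        raise ValueError(f"expected two classes, found {groups}")
    counts = labels.value_counts()

    # 3. onion balancing of the majority class
    selected_majority: list = []
    if counts[groups[0]] != counts[groups[1]]:
        major = counts.idxmax()
        minor_n = int(counts.min())
        k = config.design_k or math.ceil(1.2 * minor_n)
        maj_ids = labels.index[labels == major]
        k = min(k, len(maj_ids))
        X_maj = log_center(norm.study.loc[kept]).loc[maj_ids]
        A_maj = choose_components_by_variance(X_maj, config.variance_target)
        pca_maj = fit_pca(X_maj, A_maj)
        rep_maj = outlier_test(pca_maj, X_maj, alpha=config.alpha)
        cand = CandidateSet.from_scores_and_q(
            pca_maj.scores, rep_maj.q.to_numpy(), maj_ids
        )
        n_layers = min(config.n_layers, max(1, k))
        sel = onion_select(cand, k, n_layers=n_layers, rng=seeds[1])
        selected_majority = list(sel.selected_ids)
        balanced_ids = selected_majority + list(labels.index[labels != major])
    else:
        balanced_ids = list(labels.index)

    bal_labels = labels.loc[balanced_ids]
    X_bal = log_center(norm.study.loc[balanced_ids]).to_numpy()
    y_bal = bal_labels.to_numpy()

    # 4. PLS2C stability selection + permutation
    cv = CVScheme(repeats=1, folds=config.cv_folds, seed=seeds[2])
    stab = stability_selection(
        X_bal,
        y_bal,
        n_sub=config.n_sub,
        n_components=config.n_components,
        cv_scheme=cv,
        rng=seeds[2],
        feature_ids=norm.feature_ids,
    )
    perm_cv = CVScheme(repeats=1, folds=config.cv_folds, seed=seeds[3])

    def pls_stat(X, y):
        return repeated_cv_mcc(PLSClassifier(stab.n_components), X, y, perm_cv)

    p_pls, _, _ = permutation_test(pls_stat, X_bal, y_bal, n_perm=config.n_perm, rng=seeds[3])

    # 5. random forest through the same harness
    rf_factory = random_forest_factory(seed=seeds[4], n_estimators=config.rf_trees)
    mcc_rf = oob_mcc(rf_factory, X_bal, y_bal, n_models=50, rng=seeds[4])
    rf_perm_factory = random_forest_factory(seed=seeds[4], n_estimators=100)

    def rf_stat(X, y):
        return repeated_cv_mcc(rf_perm_factory(), X, y, perm_cv)

    p_rf, _, _ = permutation_test(rf_stat, X_bal, y_bal, n_perm=config.n_perm, rng=seeds[5])

    # 6. univariate screen on the balanced, normalized (un-logged) set
    from .univariate import volcano_table

    bal_table = norm.select_samples(
        [i for i in norm.intensities.index if i in set(balanced_ids) or norm.roles[i] != "Study"]
    )
    volcano = volcano_table(bal_table, groups=groups)

    rep = ComparisonReport(
        filter_report=report.to_frame(),
        outliers=outliers,
        n_components_pca=A,
        selected_majority=selected_majority,
        mcc_oob_pls=stab.mcc_oob,
        perm_p_pls=p_pls,
        mcc_oob_rf=mcc_rf,
        perm_p_rf=p_rf,
        n_components_pls=stab.n_components,
        relevant_features=stab.relevant_features(),
        selection_frequency=stab.selection_frequency,
        volcano=volcano,
        seed=config.seed,
    )
    if config.outdir:
        rep.write(config.outdir)
    return rep
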