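"""Synthetic urinary-metabolomics cohorts with known ground truth.

Emulates the statistical structure an untargeted LC-MS urine study
presents to the analysis pipeline: log-normal feature intensities with
feature-specific location and spread, a configurable set of
class-discriminant features shifted on the log scale, per-sample
multiplicative dilution (urine concentration varies widely between
newborns), pooled QC samples with a target coefficient of variation,
low-level blank contamination, and intensity-dependent (left-censoring
like) missingness. Every stage of the pipeline is therefore testable
against known truth without any external data.

Nothing at the chromatogram/spectrum level is simulated (no mzML, no
retention-time drift, no batch effects).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import FeatureTable


@dataclass
class SimConfig:
    """Parameters of the simulated cohort.

    Attributes
    ----------
    n_per_group : int
        Study samples per class (two classes, labelled "case"/"control").
    n_features : int
        Number of Rt_mass features.
    n_discriminant : int
        Number of features shifted between classes.
    effect_size : float
        Standardized between-class mean shift of discriminant features,
        in units of the within-group SD on the log scale.
    dilution_range : tuple[float, float]
        Per-sample multiplicative dilution factors drawn uniformly from
        [lo, hi]; lo > 0.
    qc_count, blank_count : int
        Numbers of pooled-QC and blank injections (each >= 3).
    blank_level : float
        Baseline blank intensity as a fraction of the median study
        intensity of the feature, in [0, 1].
    n_contaminated : int
        Features given strong (0.5 x median) blank signal, so the
        blank-ratio filter has true positives.
    missing_rate : float
        Probability that a value in the lowest intensity decile of its
        feature is missing.
    qc_cv_target : float
        Target coefficient of variation of QC replicates.
    seed : int
        Global RNG seed; fans out to independent per-stage child seeds.
    """

    n_per_group: int = 30
    n_features: int = 500
    n_discriminant: int = 10
    effect_size: float = 2.0
    dilution_range: tuple[float, float] = (0.5, 2.0)
    qc_count: int = 10
    blank_count: int = 5
    blank_level: float = 0.02
    n_contaminated: int = 10
    missing_rate: float = 0.3
    qc_cv_target: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0 or self.n_features <= 0:
            raise ValueError("n_per_group and n_features must be positive")
        if not 0 <= self.n_discriminant <= self.n_features:
            raise ValueError("need 0 <= n_discriminant <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        lo, hi = self.dilution_range
        if not (0 < lo <= hi):
            raise ValueError("dilution_range must satisfy 0 < lo <= hi")
        if self.qc_count < 3 or self.blank_count < 3:
            raise ValueError("need at least 3 QCs and 3 blanks")
        for name in ("blank_level", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.n_contaminated <= self.n_features:
            raise ValueError("n_contaminated must be in [0, n_features]")
        if self.qc_cv_target < 0:
            raise ValueError("qc_cv_target must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream verification."""

    discriminant_indices: list[int]
    contaminated_indices: list[int]
    dilution_factors: pd.Series  # per study sample
    class_labels: pd.Series  # per study sample

    def to_json(self, path: str | Path) -> None:
        payload = {
            "discriminant_indices": list(map(int, self.discriminant_indices)),
            "contaminated_indices": list(map(int, self.contaminated_indices)),
            "dilution_factors": {k: float(v) for k, v in self.dilution_factors.items()},
            "class_labels": {k: str(v) for k, v in self.class_labels.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            d["discriminant_indices"],
            d["contaminated_indices"],
            pd.Series(d["dilution_factors"]),
            pd.Series(d["class_labels"]),
        )


def _feature_ids(rng: np.random.Generator, m: int) -> list[str]:
    """Rt_mass-style ids, e.g. '1.23_180.0634' (unique by construction)."""
    rt = rng.uniform(0.4, 8.0, m)
    mz = rng.uniform(50, 1000, m)
    ids, seen = [], set()
    for r, z in zip(rt, mz):
        fid = f"{r:.2f}_{z:.4f}"
        while fid in seen:
            z += 0.0001
            fid = f"{r:.2f}_{z:.4f}"
        seen.add(fid)
        ids.append(fid)
    return ids


def generate_cohort(config: SimConfig) -> tuple[FeatureTable, GroundTruth]:
    """Simulate a two-class cohort with QCs and blanks.

    Study intensities are log-normal with per-feature random location
    and spread; class "case" is shifted up by ``effect_size`` within-SD
    units on the log scale for the planted features. Each study sample
    is then multiplied by its dilution factor. QC rows are per-feature
    means of the (undiluted) study samples times multiplicative
    log-normal noise calibrated to ``qc_cv_target`` — mirroring a pooled
    aliquot of every sample. Blanks carry ``blank_level`` background
    plus strong signal in ``n_contaminated`` features. Finally, values
    in the lowest intensity decile of each feature go missing with
    probability ``missing_rate``.

    Deterministic: a fixed seed yields bit-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("ids", "base", "study", "dilution", "qc", "blank", "missing"),
            ss.spawn(7),
        )
    }

    m = config.n_features
    n = 2 * config.n_per_group
    feature_ids = _feature_ids(rngs["ids"], m)

    # per-feature log-scale location and spread: wide concentration range
    mu = rngs["base"].uniform(np.log(1e4), np.log(1e6), m)
    sigma = rngs["base"].uniform(0.2, 0.8, m)
    disc = np.sort(rngs["base"].choice(m, size=config.n_discriminant, replace=False))

    labels = np.array(["case"] * config.n_per_group + ["control"] * config.n_per_group)
    shift = np.zeros((n, m))
    shift[np.ix_(labels == "case", disc)] = (config.effect_size * sigma[disc])[None, :]

    log_x = mu[None, :] + shift + rngs["study"].normal(0.0, 1.0, (n, m)) * sigma[None, :]
    study = np.exp(log_x)

    lo, hi = config.dilution_range
    dilution = rngs["dilution"].uniform(lo, hi, n)
    study_diluted = study * dilution[:, None]

    # QC = pooled mean of the study samples, with multiplicative noise
    # whose log-SD is calibrated so the realized CV matches the target
    pooled = study.mean(axis=0)
    s = np.sqrt(np.log1p(config.qc_cv_target**2))
    qc_noise = np.exp(rngs["qc"].normal(0.0, s, (config.qc_count, m)) - s**2 / 2)
    qc = pooled[None, :] * qc_noise

    med = np.median(study, axis=0)
    contaminated = np.sort(
        rngs["blank"].choice(m, size=config.n_contaminated, replace=False)
    )
    blank_base = config.blank_level * med
    blank_base = np.where(np.isin(np.arange(m), contaminated), 0.5 * med, blank_base)
    blank = blank_base[None, :] * np.exp(
        rngs["blank"].normal(0.0, 0.3, (config.blank_count, m))
    )

    values = np.vstack([study_diluted, qc, blank])
    sample_ids = (
        [f"S{i + 1:03d}" for i in range(n)]
        + [f"QC{i + 1:02d}" for i in range(config.qc_count)]
        + [f"B{i + 1:02d}" for i in range(config.blank_count)]
    )
    roles = ["Study"] * n + ["QC"] * config.qc_count + ["Blank"] * config.blank_count

    # intensity-dependent missingness: lowest decile of each feature
    decile = np.quantile(values, 0.10, axis=0)
    at_risk = values < decile[None, :]
    dropped = at_risk & (rngs["missing"].random(values.shape) < config.missing_rate)
    values = np.where(dropped, np.nan, values)

    intensities = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    roles_s = pd.Series(roles, index=sample_ids)
    labels_s = pd.Series(
        list(labels) + [np.nan] * (config.qc_count + config.blank_count),
        index=sample_ids,
    )
    table = FeatureTable(intensities, roles_s, labels_s)
    truth = GroundTruth(
        discriminant_indices=list(map(int, disc)),
        contaminated_indices=list(map(int, contaminated)),
        dilution_factors=pd.Series(dilution, index=sample_ids[:n]),
        class_labels=pd.Series(labels, index=sample_ids[:n]),
    )
    return table, truth


def generate_metadata(
    n: int,
    factor_prevalences: dict[str, float],
    outcome_prevalence: float = 0.2,
    associated_factor: str | None = None,
    odds_ratio: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary cohort metadata (risk factors) plus a binary outcome.

    Factors are independent Bernoulli variables at the stated
    prevalences. The outcome is Bernoulli with base prevalence
    ``outcome_prevalence``; if ``associated_factor`` is given, carriers
    of that factor have their odds of the outcome multiplied by
    ``odds_ratio`` (all other factors stay null).
    """
    for name, p in factor_prevalences.items():
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence of {name!r} outside [0, 1]")
    if not 0 < outcome_prevalence < 1:
        raise ValueError("outcome_prevalence must be in (0, 1)")
    if associated_factor is not None and associated_factor not in factor_prevalences:
        raise ValueError(f"unknown associated_factor {associated_factor!r}")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")

    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            name: (rng.random(n) < p).astype(int)
            for name, p in factor_prevalences.items()
        },
        index=[f"S{i + 1:03d}" for i in range(n)],
    )
    logit = np.log(outcome_prevalence / (1 - outcome_prevalence)) * np.ones(n)
    if associated_factor is not None:
        logit = logit + np.log(odds_ratio) * df[associated_factor].to_numpy()
    p_out = 1 / (1 + np.exp(-logit))
    df["outcome"] = (rng.random(n) < p_out).astype(int)
    return df
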