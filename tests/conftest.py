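import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from uromet import FeatureTable, SimConfig, generate_cohort, preprocess

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (30+30 study, 10 planted features, 500 total)."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def preprocessed(cohort):
    table, truth = cohort
    norm, quotients, report = preprocess(table)
    return norm, quotients, report, truth


def make_table(study, qc, blank, labels=None, feature_ids=None):
    """Hand-built FeatureTable from row lists (NaN = missing)."""
    study = np.atleast_2d(np.asarray(study, dtype=float))
    qc = np.atleast_2d(np.asarray(qc, dtype=float))
    blank = (
        np.atleast_2d(np.asarray(blank, dtype=float))
        if blank is not None
        else np.empty((0, study.shape[1]))
    )
    m = study.shape[1]
    ids = feature_ids or [f"{i + 1}.00_{100 + i}.0000" for i in range(m)]
    rows = np.vstack([study, qc, blank])
    names = (
        [f"S{i + 1}" for i in range(len(study))]
        + [f"QC{i + 1}" for i in range(len(qc))]
        + [f"B{i + 1}" for i in range(len(blank))]
    )
    roles = ["Study"] * len(study) + ["QC"] * len(qc) + ["Blank"] * len(blank)
    lab = list(labels) if labels is not None else [np.nan] * len(study)
    lab = lab + [np.nan] * (len(qc) + len(blank))
    return FeatureTable(
        pd.DataFrame(rows, index=names, columns=ids),
        pd.Series(roles, index=names),
        pd.Series(lab, index=names),
    )
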