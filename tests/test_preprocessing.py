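"""Filtering cascade, imputation, PQN and scaling."""

import numpy as np
import pandas as pd
import pytest

from uromet import (
    filter_missing_in_qc,
    filter_blank_ratio,
    filter_qc_cv,
    impute_missing,
    pqn_normalize,
    log_center,
)
from conftest import make_table

NA = np.nan


class TestMissingInQC:
    def test_feature_with_missing_qc_removed_study_missingness_ignored(self):
        # f1: one of 5 QCs missing -> removed; f2: complete QCs but 50%
        # missing in Study -> retained
        study = [[1, NA], [2, 5], [NA, 6], [4, NA]]
        qc = [[1, 1], [2, 1], [NA, 1], [4, 1], [5, 1]]
        t = make_table(study, qc, [[0.1, 0.1]])
        out, rep = filter_missing_in_qc(t)
        assert out.feature_ids == [t.feature_ids[1]]
        assert rep.steps == [("missing_in_qc", 1)]

    def test_surviving_count(self):
        rng = np.random.default_rng(0)
        qc = rng.uniform(1, 2, (5, 10))
        qc[0, [2, 5, 7]] = NA  # 3 features with a QC hole
        t = make_table(rng.uniform(1, 2, (4, 10)), qc, rng.uniform(0, 0.1, (2, 10)))
        out, rep = filter_missing_in_qc(t)
        assert out.n_features == 7 and rep.surviving == 7

    def test_requires_qc_rows(self):
        t = make_table([[1.0]], np.empty((0, 1)), [[0.1]])
        with pytest.raises(ValueError, match="QC"):
            filter_missing_in_qc(t)


class TestBlankRatio:
    def test_threshold_decisions(self):
        # f1: P95(B)=25, P5(QC)=100 -> 0.25 > 0.2 removed
        # f2: absent in blanks -> ratio 0, retained
        qc = [[100.0, 100], [100, 100], [100, 100]]
        blank = [[25.0, 0], [25, 0], [25, 0]]
        t = make_table([[1.0, 1]], qc, blank)
        out, rep = filter_blank_ratio(t)
        assert out.feature_ids == [t.feature_ids[1]]

    def test_percentile_rule_matches_sorted_order_oracle(self):
        blanks = np.array([10.0, 10, 10, 30])
        qcs = np.array([100.0] * 5)
        # linear-interpolation oracle: P95 of sorted blanks
        s = np.sort(blanks)
        h = 0.95 * (len(s) - 1)
        p95 = s[int(h)] + (h - int(h)) * (s[int(h) + 1] - s[int(h)])
        t = make_table([[1.0]], qcs[:, None], blanks[:, None])
        out, _ = filter_blank_ratio(t, threshold=0.20)
        keep_oracle = p95 / 100.0 <= 0.20
        assert (out.n_features == 1) == keep_oracle

    def test_missing_blank_treated_as_zero(self):
        t = make_table([[1.0]], [[100.0], [100], [100]], [[NA], [NA], [NA]])
        out, _ = filter_blank_ratio(t)
        assert out.n_features == 1

    def test_requires_blank_rows(self):
        t = make_table([[1.0]], [[1.0]], None)
        with pytest.raises(ValueError, match="Blank"):
            filter_blank_ratio(t)


class TestQCCV:
    def test_zero_cv_retained_high_cv_removed(self):
        # f1 constant (CV 0), f2 CV ~ 0.283 > 0.2
        qc = [[100.0, 100], [100, 150]]
        t = make_table([[1.0, 1]], qc, [[0.0, 0]])
        cv2 = np.std([100, 150], ddof=1) / np.mean([100, 150])
        assert cv2 == pytest.approx(0.2828, abs=1e-4)
        out, rep = filter_qc_cv(t)
        assert out.feature_ids == [t.feature_ids[0]]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.uniform(1, 2, (3, 20)), rng.uniform(1, 2, (4, 20)),
                       rng.uniform(0, 0.01, (2, 20)))
        once, _ = filter_qc_cv(t)
        twice, rep = filter_qc_cv(once)
        assert twice.feature_ids == once.feature_ids
        assert rep.steps[-1][1] == 0

    def test_requires_two_qcs(self):
        t = make_table([[1.0]], [[1.0]], [[0.0]])
        with pytest.raises(ValueError):
            filter_qc_cv(t)


class TestImpute:
    def test_draws_strictly_inside_zero_min(self):
        study = [[50.0, 5], [NA, 5], [80, NA], [NA, 5]]
        t = make_table(study, [[60.0, 5], [70, 5]], [[0.1, 0.1]])
        out = impute_missing(t, np.random.default_rng(0))
        filled = out.intensities.to_numpy()
        assert not np.isnan(filled).any()
        assert 0 < filled[1, 0] < 50 and 0 < filled[3, 0] < 50
        assert 0 < filled[2, 1] < 5
        # observed entries untouched
        assert filled[0, 0] == 50 and filled[2, 0] == 80

    def test_identity_without_missing(self):
        t = make_table([[1.0, 2]], [[1.0, 2]], [[0.1, 0.1]])
        out = impute_missing(t, 0)
        pd.testing.assert_frame_equal(out.intensities, t.intensities)

    def test_deterministic_under_seed(self):
        study = [[NA, 5], [3, NA], [9, 7]]
        t = make_table(study, [[5.0, 5]], [[0.1, 0.1]])
        a = impute_missing(t, np.random.default_rng(42)).intensities
        b = impute_missing(t, np.random.default_rng(42)).intensities
        pd.testing.assert_frame_equal(a, b)

    def test_entirely_missing_feature_is_error(self):
        t = make_table([[NA], [NA]], [[NA]], [[NA]])
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(t, 0)


class TestPQN:
    def test_sample_equal_to_reference_unchanged(self):
        ref = np.array([10.0, 20, 30, 40])
        t = make_table([ref.tolist()], [ref.tolist()] * 3, [[0, 0, 0, 0]])
        out, q = pqn_normalize(t)
        assert q["S1"] == pytest.approx(1.0)
        assert np.allclose(out.study.to_numpy()[0], ref)

    def test_exact_dilution_removal(self):
        ref = np.array([10.0, 20, 30, 40])
        t = make_table([(3 * ref).tolist()], [ref.tolist()] * 3, [[0, 0, 0, 0]])
        out, q = pqn_normalize(t)
        assert q["S1"] == pytest.approx(3.0)
        assert np.allclose(out.study.to_numpy()[0], ref)

    def test_quotients_recover_true_dilution(self, preprocessed):
        norm, quotients, _, truth = preprocessed
        q = quotients.loc[truth.dilution_factors.index]
        r = np.corrcoef(q, truth.dilution_factors)[0, 1]
        assert r > 0.99

    def test_restores_dilution_only_perturbation(self, preprocessed):
        norm, _, _, _ = preprocessed
        rng = np.random.default_rng(0)
        d = rng.uniform(0.5, 2.0, norm.study.shape[0])
        pert = norm.copy()
        mask = pert.roles == "Study"
        pert.intensities.loc[mask] = pert.intensities.loc[mask].mul(d, axis=0)
        restored, _ = pqn_normalize(pert)
        rel = np.abs(restored.study.to_numpy() / norm.study.to_numpy() - 1)
        assert rel.max() < 0.01

    def test_zero_reference_is_error(self):
        t = make_table([[1.0]], [[0.0], [0.0]], [[0.0]])
        with pytest.raises(ValueError, match="reference"):
            pqn_normalize(t)


class TestLogCenter:
    def test_constant_e_column_maps_to_zero(self):
        m = pd.DataFrame({"f": [np.e, np.e, np.e]})
        out = log_center(m)
        assert np.allclose(out["f"], 0.0)

    def test_column_means_vanish_and_shape_preserved(self, preprocessed):
        norm, _, _, _ = preprocessed
        out = log_center(norm.study)
        assert out.shape == norm.study.shape
        assert np.abs(out.mean(axis=0)).max() < 1e-10

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_center(pd.DataFrame({"f": [1.0, 0.0]}))


class TestCascade:
    def test_counts_telescope(self, preprocessed):
        _, _, report, _ = preprocessed
        frame = report.to_frame()
        assert frame["surviving"].iloc[-1] == report.surviving
        assert report.initial - sum(n for _, n in report.steps) == report.surviving

    def test_order_of_rules(self, preprocessed):
        _, _, report, _ = preprocessed
        assert [r for r, _ in report.steps] == [
            "missing_in_qc", "blank_ratio", "qc_cv", "qc_cv_post_norm",
        ]

    def test_contaminated_features_removed(self, cohort, preprocessed):
        table, truth = cohort
        norm, _, _, _ = preprocessed
        contaminated = set(np.array(table.feature_ids)[truth.contaminated_indices])
        assert not contaminated & set(norm.feature_ids)

    def test_filters_never_alter_retained_values(self, cohort):
        table, _ = cohort
        t1, _ = filter_missing_in_qc(table)
        t2, _ = filter_blank_ratio(t1)
        t3, _ = filter_qc_cv(t2)
        pd.testing.assert_frame_equal(
            t3.intensities, table.intensities[t3.feature_ids]
        )
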