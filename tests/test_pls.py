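"""NIPALS PLS2, VIP, component selection, stability selection, permutation."""

import numpy as np
import pytest

import uromet.pls as pls_mod
from uromet import (
    PLSClassifier,
    dummy_code,
    fit_pls2,
    classify,
    vip,
    select_components,
    stability_selection,
    permutation_test,
)
from uromet.validation import CVScheme


def _two_cluster_data(n=20, p=10, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X[y == "b", 0] += gap
    return X, y


class TestFit:
    def test_collinear_response_exact_fit(self):
        # one component suffices when the informative column is orthogonal
        # to the rest: the first latent direction is exactly that column
        rng = np.random.default_rng(0)
        # orthonormal columns that are also orthogonal to the constant
        # vector, so centering leaves them untouched
        M = np.column_stack([np.ones(15), rng.normal(size=(15, 4))])
        X = np.linalg.qr(M)[0][:, 1:]
        y = 2.5 * X[:, 2]
        m = fit_pls2(X, y, 1)
        assert np.abs(m.predict_response(X)[:, 0] - y).max() < 1e-8

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 6))
        Y = rng.normal(size=(25, 2))
        m = fit_pls2(X, Y, 6)
        Xc = X - X.mean(0)
        beta = np.linalg.lstsq(Xc, Y - Y.mean(0), rcond=None)[0]
        fitted_ols = Xc @ beta + Y.mean(0)
        assert np.abs(m.predict_response(X) - fitted_ols).max() < 1e-6

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(2)
        m = fit_pls2(rng.normal(size=(30, 12)), rng.normal(size=30), 4)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_single_column_response_matches_two_column_dummy(self):
        """PLS2 on a dummy pair reduces to PLS1 on the contrast."""
        X, y = _two_cluster_data()
        Y, classes = dummy_code(y)
        m2 = fit_pls2(X, Y, 2)
        m1 = fit_pls2(X, Y[:, 0], 2)
        contrast2 = m2.predict_response(X)[:, 0]
        assert np.allclose(contrast2, m1.predict_response(X)[:, 0], atol=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_pls2(np.ones((10, 3)), np.arange(10.0), 1)

    def test_excess_components_rejected(self):
        u = np.arange(10.0)[:, None]
        X = u @ np.array([[1.0, 2.0]])  # rank 1
        with pytest.raises(ValueError):
            fit_pls2(X, np.arange(10.0), 2)


class TestClassify:
    def test_larger_dummy_prediction_wins(self):
        X, y = _two_cluster_data()
        clf = PLSClassifier(2).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_tie_breaks_to_lower_label_index(self):
        X, y = _two_cluster_data()
        m = PLSClassifier(1).fit(X, y).model_
        # a sample at the training mean predicts the class means of the
        # dummy response: an exact tie for balanced classes
        tied = classify(m, m.x_mean[None, :])
        assert tied[0] == m.classes[0]

    def test_separable_data_perfect_training_mcc(self):
        from uromet import mcc_from_labels

        X, y = _two_cluster_data(gap=10.0)
        clf = PLSClassifier(2).fit(X, y)
        assert mcc_from_labels(y, clf.predict(X)) == 1.0


class TestVIP:
    def test_sum_of_squares_equals_feature_count(self):
        rng = np.random.default_rng(3)
        for p in (5, 20):
            m = fit_pls2(rng.normal(size=(30, p)), rng.normal(size=30), 3)
            v = vip(m)
            assert v @ v == pytest.approx(p, abs=1e-8)

    def test_informative_feature_ranks_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 51))
            y = np.array(["a"] * 20 + ["b"] * 20)
            X[y == "b", 0] += 2.0
            Y, _ = dummy_code(y)
            m = fit_pls2(X, Y, 2)
            hits += int(np.argmax(vip(m)) == 0)
        assert hits >= 19

    def test_symmetric_features_get_equal_vip(self):
        rng = np.random.default_rng(4)
        n = 40
        y = np.array([0.0] * 20 + [1.0] * 20)
        base = rng.normal(size=n)
        X = np.column_stack([y + base * 0.1, y + base * 0.1, rng.normal(size=n)])
        m = fit_pls2(X, y, 1)
        v = vip(m)
        assert abs(v[0] - v[1]) < 1e-6


class TestSelectComponents:
    def test_first_maximum_rule_with_tie_toward_smaller(self, monkeypatch):
        seq = {1: 0.3, 2: 0.5, 3: 0.5, 4: 0.4}
        monkeypatch.setattr(
            pls_mod, "repeated_cv_mcc",
            lambda learner, X, y, scheme: seq[learner.n_components],
        )
        X = np.random.default_rng(0).normal(size=(30, 10))
        y = np.array(["a", "b"] * 15)
        assert select_components(X, y, a_max=4) == 2

    def test_monotone_increase_returns_a_max(self, monkeypatch):
        monkeypatch.setattr(
            pls_mod, "repeated_cv_mcc",
            lambda learner, X, y, scheme: 0.1 * learner.n_components,
        )
        X = np.random.default_rng(0).normal(size=(30, 10))
        y = np.array(["a", "b"] * 15)
        assert select_components(X, y, a_max=3) == 3

    def test_a_max_one(self):
        X, y = _two_cluster_data()
        assert select_components(X, y, a_max=1, cv_scheme=CVScheme(2, 5, 0)) == 1

    def test_two_latent_signal_recovers_two_components(self):
        # the informative block is contaminated by a dominant nuisance
        # latent; a second component (via the pure-nuisance block) is
        # needed to cancel it, so the first MCCcv maximum sits at A = 2
        picks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 60
            y = np.array(["a"] * 30 + ["b"] * 30)
            cls = (y == "b").astype(float) * 2 - 1
            informative = cls + rng.normal(scale=0.7, size=n)
            nuisance = rng.normal(scale=3.0, size=n)
            X = np.zeros((n, 20))
            X[:, :10] = np.outer(informative + nuisance, rng.normal(size=10))
            X[:, 10:] = np.outer(nuisance, rng.normal(size=10))
            X += rng.normal(scale=0.5, size=X.shape)
            picks.append(select_components(X, y, a_max=4, cv_scheme=CVScheme(3, 5, seed)))
        assert np.bincount(picks).argmax() == 2


class TestStability:
    def test_planted_recovery_with_ground_truth(self, cohort, preprocessed):
        from uromet import log_center

        table, truth = cohort
        norm, _, _, _ = preprocessed
        planted = set(np.array(table.feature_ids)[truth.discriminant_indices])
        X = log_center(norm.study).to_numpy()
        y = norm.study_labels.to_numpy()
        stab = stability_selection(X, y, n_sub=50, n_components=2, rng=1,
                                   feature_ids=norm.feature_ids)
        freq = stab.selection_frequency
        planted_freq = freq[[f for f in freq.index if f in planted]]
        other_freq = freq[[f for f in freq.index if f not in planted]]
        assert planted_freq.median() > 0.6
        assert planted_freq.median() > other_freq.max()
        assert stab.mcc_oob > 0.5

    def test_permuted_labels_kill_performance(self, preprocessed):
        from uromet import log_center

        norm, _, _, _ = preprocessed
        X = log_center(norm.study).to_numpy()
        y = np.random.default_rng(0).permutation(norm.study_labels.to_numpy())
        stab = stability_selection(X, y, n_sub=30, n_components=2, rng=2)
        assert abs(stab.mcc_oob) < 0.25

    def test_deterministic_under_seed(self):
        X, y = _two_cluster_data(n=24, p=30, gap=2.0)
        a = stability_selection(X, y, n_sub=15, n_components=2, rng=9)
        b = stability_selection(X, y, n_sub=15, n_components=2, rng=9)
        assert (a.selection_frequency == b.selection_frequency).all()
        assert a.mcc_oob == b.mcc_oob
        assert (a.submodel_mcc_cv == b.submodel_mcc_cv).all()

    def test_tiny_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError):
            stability_selection(X, y, n_sub=5)


class TestPermutation:
    def test_add_one_convention_when_observed_beats_all(self):
        y0 = np.array(["a"] * 10 + ["b"] * 10)

        def stat(X, y):
            return 1.0 if (y == y0).all() else 0.0

        X = np.zeros((20, 2))
        p, obs, perms = permutation_test(stat, X, y0, n_perm=1000, rng=0)
        assert p == pytest.approx(1 / 1001)
        assert obs == 1.0

    def test_median_statistic_gives_half(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 1))
        y = np.array(["a", "b"] * 20)

        def stat(X_, y_):
            return float(np.mean(X_[y_ == "a", 0]))

        p, _, perms = permutation_test(stat, X, y, n_perm=999, rng=1)
        # observed is itself a draw from the permutation distribution
        assert 0.1 < p < 0.9

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for rep in range(400):
            X = rng.normal(size=(30, 1))
            y = np.array(["a"] * 15 + ["b"] * 15)

            def stat(X_, y_):
                return abs(np.mean(X_[y_ == "a", 0]) - np.mean(X_[y_ == "b", 0]))

            p, _, _ = permutation_test(stat, X, y, n_perm=99, rng=rep)
            ps.append(p)
        from scipy.stats import kstest

        d = kstest(ps, "uniform").statistic
        assert d < 0.1

    def test_nperm_below_one_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(lambda X, y: 0.0, np.zeros((4, 1)),
                             np.array([0, 0, 1, 1]), n_perm=0)
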