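"""Feature selection, cross-validated classification and Mahalanobis scatter."""

from __future__ import annotations

import numpy as np
import pytest

from mxbrain.classify import (
    evaluate,
    lasso_select,
    mahalanobis_scatter,
    prefilter_significant,
)
from mxbrain.errors import EmptySelectionError, ParameterError


def two_blob_data(rng, n_per_class=10, n_noise=8, sep=4.0):
    """One informative dimension separating the classes plus noise columns."""
    n = 2 * n_per_class
    X = rng.standard_normal((n, 1 + n_noise))
    X[n_per_class:, 0] += sep
    y = np.array(["control"] * n_per_class + ["patient"] * n_per_class)
    names = ["signal"] + [f"noise{j}" for j in range(n_noise)]
    return X, y, names


class TestPrefilter:
    def test_keeps_only_significant(self):
        p = {"a": 0.01, "b": 0.2, "c": 0.04}
        assert prefilter_significant(["a", "b", "c"], p) == ["a", "c"]

    def test_all_significant_is_identity(self):
        p = {"a": 0.01, "b": 0.02}
        assert prefilter_significant(["a", "b"], p) == ["a", "b"]

    def test_empty_survivor_set_errors(self):
        with pytest.raises(EmptySelectionError):
            prefilter_significant(["a"], {"a": 0.9})


class TestLassoSelect:
    def test_informative_feature_is_kept_and_noise_mostly_dropped(self):
        hits, noise_picks, total_noise = 0, 0, 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X, y, names = two_blob_data(rng)
            chosen = lasso_select(X, y, names, seed=seed)
            hits += "signal" in chosen
            noise_picks += sum(1 for f in chosen if f.startswith("noise"))
            total_noise += len(names) - 1
        assert hits >= 48
        assert noise_picks / total_noise < 0.2

    def test_duplicated_informative_feature_never_gets_opposing_large_weights(self):
        # L1 splits or picks one duplicate; it must not cancel one against
        # the other - check via the selected set (never both with opposite
        # signs of large magnitude, which selection would expose as both in)
        from sklearn.linear_model import LogisticRegressionCV
        from sklearn.preprocessing import StandardScaler

        rng = np.random.default_rng(0)
        X, y, names = two_blob_data(rng, n_noise=0)
        X2 = np.column_stack([X[:, 0], X[:, 0]])
        Xs = StandardScaler().fit_transform(X2)
        model = LogisticRegressionCV(
            l1_ratios=(1,), solver="liblinear", Cs=8, cv=3, random_state=0,
            max_iter=2000, scoring="accuracy", use_legacy_attributes=False,
        ).fit(Xs, y)
        c = model.coef_.ravel()
        assert not (c[0] * c[1] < 0 and min(abs(c)) > 0.5)

    def test_empty_selection_falls_back_to_full_set_with_warning(self):
        # a penalty strong enough to zero every coefficient must trigger the
        # documented fallback instead of returning nothing
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 6))
        y = np.array(["control"] * 10 + ["patient"] * 10)
        names = [f"n{j}" for j in range(6)]
        with pytest.warns(UserWarning, match="zero"):
            chosen = lasso_select(X, y, names, seed=0, Cs=[1e-4])
        assert chosen == names

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ParameterError):
            lasso_select(X, np.array(["a"] * 4), ["x", "y"])


class TestEvaluate:
    def test_separable_data_is_classified_perfectly(self):
        rng = np.random.default_rng(0)
        X, y, names = two_blob_data(rng, sep=8.0)
        report = evaluate(X, y, classifier="svm_rbf", folds=10, seed=0, feature_names=names)
        assert report.accuracy == 100.0
        assert report.auc == pytest.approx(1.0)

    def test_confusion_matrix_consistency(self):
        rng = np.random.default_rng(1)
        X, y, names = two_blob_data(rng, sep=1.0)
        r = evaluate(X, y, classifier="svm_linear", folds=5, seed=1, feature_names=names)
        c = r.confusion
        n = sum(c.values())
        assert n == len(y)
        assert r.accuracy == pytest.approx(100.0 * (c["tp"] + c["tn"]) / n)
        assert r.sensitivity == pytest.approx(100.0 * c["tp"] / (c["tp"] + c["fn"]))
        assert r.specificity == pytest.approx(100.0 * c["tn"] / (c["tn"] + c["fp"]))

    def test_roc_is_monotone(self):
        rng = np.random.default_rng(2)
        X, y, names = two_blob_data(rng, sep=2.0)
        r = evaluate(X, y, classifier="svm_rbf", folds=5, seed=2, feature_names=names)
        assert np.all(np.diff(r.roc[:, 0]) >= 0)
        assert np.all(np.diff(r.roc[:, 1]) >= 0)

    def test_seeded_cv_is_reproducible(self):
        rng = np.random.default_rng(3)
        X, y, names = two_blob_data(rng, sep=2.0)
        a = evaluate(X, y, folds=5, seed=7, feature_names=names)
        b = evaluate(X, y, folds=5, seed=7, feature_names=names)
        assert a.accuracy == b.accuracy and a.auc == b.auc
        assert np.array_equal(a.roc, b.roc)

    def test_pure_noise_stays_at_chance(self):
        # leakage canary: in-fold selection on pure noise must not create
        # above-chance accuracy
        accs = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((30, 20))
            y = np.array(["control"] * 15 + ["patient"] * 15)
            r = evaluate(X, y, folds=5, seed=seed)
            accs.append(r.accuracy / 100.0)
        # binomial sd of the mean over 8 x 30 predictions ~ 0.032
        assert abs(np.mean(accs) - 0.5) < 0.13

    @pytest.mark.parametrize("clf", ["svm_rbf", "svm_linear", "knn", "naive_bayes", "fda"])
    def test_all_classifiers_run(self, clf):
        rng = np.random.default_rng(4)
        X, y, names = two_blob_data(rng, sep=6.0)
        r = evaluate(X, y, classifier=clf, folds=5, seed=0, feature_names=names)
        assert r.accuracy >= 90.0

    def test_grouped_folds_keep_subjects_together(self):
        rng = np.random.default_rng(5)
        X, y, names = two_blob_data(rng, n_per_class=12, sep=6.0)
        groups = np.repeat([f"s{i}" for i in range(8)], 3)
        r = evaluate(X, y, folds=4, seed=0, feature_names=names, groups=groups)
        assert r.accuracy > 80.0

    def test_invalid_folds_rejected(self):
        rng = np.random.default_rng(6)
        X, y, names = two_blob_data(rng, n_per_class=4)
        with pytest.raises(ParameterError):
            evaluate(X, y, folds=10, seed=0, feature_names=names)


class TestMahalanobis:
    def test_sample_at_class_mean_has_zero_distance(self):
        rng = np.random.default_rng(0)
        Xc = rng.standard_normal((20, 2))
        Xp = rng.standard_normal((20, 2)) + 3.0
        X = np.vstack([Xc, Xp, Xc.mean(axis=0, keepdims=True)])
        y = np.array(["control"] * 20 + ["patient"] * 20 + ["control"])
        d = mahalanobis_scatter(X, y, covariance="empirical")
        assert d["d_control"].iloc[-1] == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_two_gaussian_distances_balance(self):
        rng = np.random.default_rng(1)
        Xc = rng.standard_normal((200, 2))
        Xp = rng.standard_normal((200, 2)) + np.array([4.0, 0.0])
        X = np.vstack([Xc, Xp])
        y = np.array(["control"] * 200 + ["patient"] * 200)
        d = mahalanobis_scatter(X, y, covariance="empirical")
        own = np.r_[d["d_control"][:200], d["d_patient"][200:]]
        other = np.r_[d["d_patient"][:200], d["d_control"][200:]]
        assert own.mean() < other.mean()
        assert abs(d["d_control"][:200].mean() - d["d_patient"][200:].mean()) < 0.2

    def test_two_feature_case_matches_hand_inverse(self):
        # class: 4 points with known empirical (biased) covariance
        Xc = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        sample = np.array([[3.0, 1.0]])
        X = np.vstack([Xc, Xc + 10.0, sample])
        y = np.array(["control"] * 4 + ["patient"] * 5)
        d = mahalanobis_scatter(X, y, covariance="empirical")
        # mean (1,1); biased cov = [[1,0],[0,1]] -> distance = ||(2,0)|| = 2
        assert d["d_control"].iloc[-1] == pytest.approx(2.0, abs=1e-10)

    def test_tiny_class_rejected(self):
        X = np.zeros((3, 2))
        y = np.array(["control", "patient", "patient"])
        with pytest.raises(ParameterError):
            mahalanobis_scatter(X, y)
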