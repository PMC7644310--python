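import math

import numpy as np
import pytest

import goegcn as G
from goegcn.classify import _scores

# Published confusion matrices for five breast-cancer subtype classifiers
# (three models each), stored as (TP, FP, FN, TN), and the metric values
# printed alongside them. Every cell is reproducible from its matrix to
# within half a unit in the fourth decimal place.
CONFUSIONS = {
    ("Basal", "nb"): (74, 15, 2, 342), ("Basal", "rf"): (73, 3, 3, 354),
    ("Basal", "svm"): (74, 10, 2, 347),
    ("Her2", "nb"): (29, 46, 3, 355), ("Her2", "rf"): (25, 16, 7, 385),
    ("Her2", "svm"): (28, 19, 4, 382),
    ("LumA", "nb"): (204, 38, 21, 170), ("LumA", "rf"): (195, 24, 30, 184),
    ("LumA", "svm"): (204, 32, 21, 176),
    ("LumB", "nb"): (69, 57, 13, 294), ("LumB", "rf"): (67, 25, 15, 326),
    ("LumB", "svm"): (45, 16, 37, 335),
}
PRINTED = {  # sensitivity, specificity, accuracy, F1
    ("Basal", "nb"): (0.9737, 0.9580, 0.9607, 0.8970),
    ("Basal", "rf"): (0.9605, 0.9916, 0.9861, 0.9605),
    ("Basal", "svm"): (0.9737, 0.9720, 0.9723, 0.9250),
    ("Her2", "nb"): (0.9063, 0.8853, 0.8868, 0.5421),
    ("Her2", "rf"): (0.7813, 0.9601, 0.9469, 0.6849),
    ("Her2", "svm"): (0.8750, 0.9526, 0.9469, 0.7089),
    ("LumA", "nb"): (0.9067, 0.8173, 0.8637, 0.8737),
    ("LumA", "rf"): (0.8667, 0.8846, 0.8753, 0.8784),
    ("LumA", "svm"): (0.9067, 0.8462, 0.8776, 0.8850),
    ("LumB", "nb"): (0.8415, 0.8376, 0.8383, 0.6635),
    ("LumB", "rf"): (0.8171, 0.9288, 0.9076, 0.7701),
    ("LumB", "svm"): (0.5488, 0.9544, 0.8776, 0.6294),
}


class TestMetricsFromConfusion:
    @pytest.mark.parametrize("key", sorted(CONFUSIONS))
    def test_reproduces_published_metric_cells(self, key):
        tp, fp, fn, tn = CONFUSIONS[key]
        m = G.metrics_from_confusion(G.ConfusionMatrix(tp, fp, fn, tn))
        sens, spec, acc, f1 = PRINTED[key]
        assert m["sensitivity"] == pytest.approx(sens, abs=5.001e-5)
        assert m["specificity"] == pytest.approx(spec, abs=5.001e-5)
        assert m["accuracy"] == pytest.approx(acc, abs=5.001e-5)
        assert m["f1"] == pytest.approx(f1, abs=5.001e-5)

    def test_undefined_denominators_flagged_nan(self):
        m = G.metrics_from_confusion(G.ConfusionMatrix(0, 0, 3, 5))
        assert math.isnan(m["precision"]) and math.isnan(m["f1"])
        assert m["specificity"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            G.ConfusionMatrix(-1, 0, 0, 5)


class TestAuc:
    def test_perfect_separation(self):
        assert G.auc_mann_whitney([1, 2, 3, -1, -2], [1, 1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert G.auc_mann_whitney([5, 5, 5, 5], [1, 0, 1, 0]) == 0.5

    def test_matches_all_pairs_count(self):
        scores = np.array([0.1, 0.4, 0.4, 0.8, 0.2, 0.9])
        y = np.array([0, 0, 1, 1, 0, 1])
        total = 0.0
        for sp in scores[y == 1]:
            for sn in scores[y == 0]:
                total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        expected = total / (3 * 3)
        assert G.auc_mann_whitney(scores, y) == pytest.approx(expected)
        from sklearn.metrics import roc_auc_score
        assert G.auc_mann_whitney(scores, y) == pytest.approx(roc_auc_score(y, scores))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        a1 = G.auc_mann_whitney(scores, y)
        a2 = G.auc_mann_whitney(np.exp(3 * scores) + 7, y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            G.auc_mann_whitney([1, 2], [1, 1])


class TestSmote:
    def test_zero_requested_empty(self):
        out = G.smote(np.zeros((3, 2)), k=1, n_new=0, rng=0)
        assert out.shape == (0, 2)

    def test_identical_points_reproduce_point(self):
        pts = np.tile([2.0, -1.0], (4, 1))
        out = G.smote(pts, k=2, n_new=10, rng=1)
        np.testing.assert_allclose(out, np.tile([2.0, -1.0], (10, 1)))

    def test_samples_lie_on_neighbor_segments(self):
        """Every synthetic row is within 1e-9 of a segment between a
        minority point and one of its k nearest minority neighbours."""
        rng = np.random.default_rng(2)
        minority = rng.normal(size=(12, 5))
        k = 4
        out = G.smote(minority, k=k, n_new=60, rng=3)
        d2 = ((minority[:, None, :] - minority[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1)[:, :k]
        for row in out:
            ok = False
            for i in range(12):
                for j in nn[i]:
                    a, b = minority[i], minority[j]
                    seg = b - a
                    t = np.dot(row - a, seg) / np.dot(seg, seg)
                    if -1e-9 <= t <= 1 + 1e-9:
                        dist = np.linalg.norm(row - (a + np.clip(t, 0, 1) * seg))
                        if dist < 1e-9:
                            ok = True
                            break
                if ok:
                    break
            assert ok

    def test_reproducible_under_seed(self):
        m = np.random.default_rng(4).normal(size=(6, 3))
        np.testing.assert_array_equal(G.smote(m, 3, 9, rng=7), G.smote(m, 3, 9, rng=7))

    def test_too_few_minority_rejected(self):
        with pytest.raises(ValueError):
            G.smote(np.zeros((1, 2)), k=1, n_new=1, rng=0)


class TestGaussianNB:
    def test_separated_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.3, (30, 4)), rng.normal(5, 0.3, (30, 4))])
        y = np.repeat([0, 1], 30)
        clf = G.GaussianNBClassifier().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_duplicated_features_preserve_score_ranking(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        clf1 = G.GaussianNBClassifier().fit(X, y)
        clf2 = G.GaussianNBClassifier().fit(np.hstack([X, X]), y)
        r1 = np.argsort(clf1.score_samples(X))
        r2 = np.argsort(clf2.score_samples(np.hstack([X, X])))
        np.testing.assert_array_equal(r1, r2)

    def test_posterior_matches_closed_form_densities(self):
        """Two one-feature points per class: log-odds from hand-computed
        Gaussian densities (variance floored)."""
        X = np.array([[0.0], [1.0], [10.0], [12.0]])
        y = np.array([0, 0, 1, 1])
        clf = G.GaussianNBClassifier().fit(X, y)
        x = np.array([[4.0]])
        mu0, var0 = 0.5, 0.25
        mu1, var1 = 11.0, 1.0
        def logpdf(v, mu, var):
            return -0.5 * (np.log(2 * np.pi * var) + (v - mu) ** 2 / var)
        expected = (np.log(0.5) + logpdf(4.0, mu1, var1)) - \
                   (np.log(0.5) + logpdf(4.0, mu0, var0))
        assert clf.score_samples(x)[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_sklearn_reference(self):
        from sklearn.naive_bayes import GaussianNB
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        mine = G.GaussianNBClassifier(var_floor=1e-9).fit(X, y)
        ref = GaussianNB(var_smoothing=0).fit(X, y)
        np.testing.assert_array_equal(mine.predict(X), ref.predict(X))

    def test_single_class_fit_rejected(self):
        with pytest.raises(ValueError):
            G.GaussianNBClassifier().fit(np.zeros((4, 2)), np.zeros(4))


class TestRepeatedStratifiedCV:
    def separable(self, n=100):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.2, (n // 2, 3)),
                       rng.normal(4, 0.2, (n // 2, 3))])
        y = np.repeat([0, 1], n // 2)
        return X, y

    def test_perfectly_separable_accuracy_one(self):
        X, y = self.separable()
        report = G.repeated_stratified_cv(X, y, folds=5, repeats=3, rng_seed=1)
        assert report.accuracy == 1.0
        assert report.auc == 1.0

    def test_null_auc_near_half(self):
        """Mean over independent label-independent datasets sits at chance."""
        rng = np.random.default_rng(9)
        aucs = []
        for rep in range(5):
            X = rng.normal(size=(200, 5))
            y = np.repeat([0, 1], 100)
            report = G.repeated_stratified_cv(X, y, folds=5, repeats=4,
                                              use_smote=False, rng_seed=2 + rep)
            aucs.append(report.auc)
        assert abs(float(np.mean(aucs)) - 0.5) <= 0.05

    def test_every_sample_held_out_exactly_once_per_repeat(self):
        X, y = self.separable(100)
        seen = []

        class Recorder(G.GaussianNBClassifier):
            def predict(self, Xt):
                seen.extend(map(tuple, np.asarray(Xt)))
                return super().predict(Xt)

        G.repeated_stratified_cv(X, y, Recorder, folds=5, repeats=1, rng_seed=3)
        assert sorted(seen) == sorted(map(tuple, X))

    def test_synthetic_rows_never_reach_heldout_fold(self):
        """Tag original rows with an integer provenance feature: SMOTE
        interpolation produces fractional tags, so every prediction-time
        row must carry an original (integer) tag."""
        rng = np.random.default_rng(10)
        n_min, n_maj = 12, 48
        X = np.vstack([rng.normal(0, 1, (n_min, 3)), rng.normal(2, 1, (n_maj, 3))])
        y = np.array([1] * n_min + [0] * n_maj)
        tags = np.arange(len(X), dtype=float)[:, None] * 1000
        Xt = np.hstack([X, tags])
        train_rows, test_rows = [], []

        class Recorder(G.GaussianNBClassifier):
            def fit(self, Xf, yf):
                train_rows.append(np.asarray(Xf).copy())
                return super().fit(Xf, yf)

            def predict(self, Xp):
                test_rows.append(np.asarray(Xp).copy())
                return super().predict(Xp)

        G.repeated_stratified_cv(Xt, y, Recorder, folds=4, repeats=2,
                                 use_smote=True, rng_seed=4)
        valid_tags = set(tags.ravel())
        for block in test_rows:
            assert set(block[:, -1]).issubset(valid_tags)
        # training did contain synthetic rows (fractional tags)
        assert any(len(set(b[:, -1]) - valid_tags) > 0 for b in train_rows)

    def test_smote_balances_training_classes(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 2))
        y = np.array([1] * 12 + [0] * 48)
        balanced = []

        class Recorder(G.GaussianNBClassifier):
            def fit(self, Xf, yf):
                balanced.append(int((np.asarray(yf) == 1).sum())
                                == int((np.asarray(yf) == 0).sum()))
                return super().fit(Xf, yf)

        G.repeated_stratified_cv(X, y, Recorder, folds=4, repeats=1,
                                 use_smote=True, rng_seed=5)
        assert all(balanced)

    def test_deterministic_under_seed(self):
        X, y = self.separable(60)
        r1 = G.repeated_stratified_cv(X, y, folds=5, repeats=2, rng_seed=6)
        r2 = G.repeated_stratified_cv(X, y, folds=5, repeats=2, rng_seed=6)
        assert r1.to_dict() == r2.to_dict()

    def test_impossible_stratification_rejected(self):
        X = np.zeros((10, 2))
        y = np.array([1, 1, 1] + [0] * 7)
        with pytest.raises(ValueError):
            G.repeated_stratified_cv(X, y, folds=5, repeats=1, rng_seed=0)

    def test_sklearn_estimator_satisfies_contract(self):
        from sklearn.linear_model import LogisticRegression
        X, y = self.separable(60)
        report = G.repeated_stratified_cv(
            X, y, lambda: LogisticRegression(max_iter=200), folds=3, repeats=1,
            rng_seed=7)
        assert report.accuracy == 1.0
        assert _scores(LogisticRegression(max_iter=200).fit(X, y), X).shape == (60,)
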