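import logging

import numpy as np
import pandas as pd
import pytest

from apneahrv.hrv_features import cohort_feature_table
from apneahrv.severity_classification import (
    ClassifierSpec,
    _operating_metrics,
    compare_conditions,
    cross_validated_scores,
    cutoff_sweep,
    dichotomize,
    roc_auc,
)


def auc_pairwise_oracle(scores, labels):
    """O(n^2) Mann-Whitney AUC: mean over all (pos, neg) pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestDichotomize:
    def test_boundary_is_high(self):
        labels = dichotomize(np.array([10.0, 18.0, 30.0]), 18.0)
        np.testing.assert_array_equal(labels, [False, True, True])

    def test_cutoff_below_min_flags_single_class(self, caplog):
        with caplog.at_level(logging.WARNING):
            labels = dichotomize(np.array([10.0, 20.0]), 5.0)
        assert labels.all()
        assert any("single class" in m for m in caplog.messages)

    def test_median_cutoff_balances_even_sample(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        labels = dichotomize(vals, float(np.median(vals)))
        assert labels.sum() == 2


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc(np.array([0.9, 0.8, 0.1, 0.2]),
                    np.array([True, True, False, False]))
        assert r.auc == 1.0
        assert r.auc_ci_95 == (1.0, 1.0)

    def test_all_tied_scores_give_half(self):
        r = roc_auc(np.zeros(10), np.arange(10) < 5)
        assert r.auc == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                auc_pairwise_oracle(scores, labels), abs=1e-12)

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=60) + np.repeat([0.0, 0.8], 30)
        labels = np.repeat([False, True], 30)
        r = roc_auc(scores, labels)
        lo, hi = r.auc_ci_95
        assert lo <= r.auc <= hi
        assert 0.0 <= lo < hi <= 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.ones(4), np.ones(4, dtype=bool))


class TestCrossValidation:
    @staticmethod
    def _separable(n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4))
        y = np.arange(n) % 2 == 0
        X[y] += 10.0  # disjoint supports on every feature
        return X, y

    @pytest.mark.parametrize("name", ["svm", "lda", "knn", "opls"])
    def test_perfectly_separable_auc_one(self, name):
        X, y = self._separable()
        scores = cross_validated_scores(X, y, ClassifierSpec(name),
                                        folds=5, repeats=2, seed=1)
        assert roc_auc(scores, y).auc == 1.0

    def test_same_seed_identical_scores(self):
        X, y = self._separable(seed=3)
        a = cross_validated_scores(X, y, ClassifierSpec("svm"), folds=5,
                                   repeats=2, seed=5)
        b = cross_validated_scores(X, y, ClassifierSpec("svm"), folds=5,
                                   repeats=2, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_small_class_errors_with_hint(self):
        X = np.random.default_rng(0).normal(size=(12, 3))
        y = np.arange(12) < 3
        with pytest.raises(ValueError, match="folds"):
            cross_validated_scores(X, y, ClassifierSpec("lda"), folds=5)

    def test_null_labels_auc_centred_on_half(self):
        rng = np.random.default_rng(44)
        X = rng.normal(size=(40, 5))
        aucs = []
        for k in range(100):
            y = rng.permutation(np.arange(40) % 2 == 0)
            s = cross_validated_scores(X, y, ClassifierSpec("lda"), folds=5,
                                       repeats=1, seed=k)
            aucs.append(roc_auc(s, y).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestOperatingMetrics:
    def test_accuracy_identity(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        sens, spec, acc = _operating_metrics(scores, labels)
        prev = labels.mean()
        assert acc == pytest.approx(prev * sens + (1 - prev) * spec)


@pytest.fixture(scope="module")
def cohort_features(small_cohort):
    _, records, manifest = small_cohort
    feats = cohort_feature_table(records, "belt", filtered=True)
    return feats, manifest


class TestSweepAndConditions:
    def test_all_four_classifiers_beat_chance(self, cohort_features):
        feats, manifest = cohort_features
        labels = dichotomize(manifest.response("ahi"),
                             float(np.median(manifest.response("ahi"))))
        aucs = {}
        for name in ("svm", "lda", "knn", "opls"):
            s = cross_validated_scores(feats, labels, ClassifierSpec(name),
                                       folds=4, repeats=3, seed=2)
            aucs[name] = roc_auc(s, labels).auc
        assert min(aucs.values()) > 0.6, aucs

    def test_sweep_reproducible_and_above_chance(self, cohort_features):
        feats, manifest = cohort_features
        kwargs = dict(percentiles=(25, 50, 75), folds=4, repeats=2, seed=3,
                      response_name="ahi")
        a = cutoff_sweep(feats, manifest.response("ahi"), ClassifierSpec("svm"),
                         **kwargs)
        b = cutoff_sweep(feats, manifest.response("ahi"), ClassifierSpec("svm"),
                         **kwargs)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.auc > 0.5
        assert a.optimal_cutoff in a.table["cutoff"].to_numpy()

    def test_infeasible_percentiles_skipped(self, cohort_features):
        feats, manifest = cohort_features
        sweep = cutoff_sweep(feats, manifest.response("ahi"),
                             ClassifierSpec("lda"),
                             percentiles=(5, 50, 95), folds=4, repeats=1,
                             seed=0, response_name="ahi")
        assert sweep.table["percentile"].tolist() == [50.0]

    def test_compare_conditions_smoke(self, small_cohort):
        _, records, manifest = small_cohort
        tidy, sweeps = compare_conditions(
            records, manifest, responses=("ahi",),
            specs=(ClassifierSpec("svm"),),
            percentiles=(50,), folds=4, repeats=1, seed=1,
        )
        assert len(sweeps) == 4  # belt/patch x filtered/unfiltered
        assert tidy["auc"].between(0, 1).all()
        assert set(zip(tidy["sensor"], tidy["filtered"])) == {
            ("belt", True), ("belt", False), ("patch", True), ("patch", False)}
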