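"""Confusion statistics, ROC/AUC, fold protocol and the SVM baseline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sipforest.evaluation import (
    ConfusionCounts,
    confusion,
    cross_validate,
    five_fold_split,
    metrics,
    roc_auc,
    svm_baseline,
)
from sipforest.gcforest import make_two_class_features
from conftest import small_forests


def mann_whitney_auc(y, s):
    """Pairwise concordance count with half-credit ties (independent oracle)."""
    pos = s[np.asarray(y) == 1]
    neg = s[np.asarray(y) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_total_disagreement(self):
        y = np.array([1, 1, 0, 0])
        c = confusion(y, 1 - y)
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_matches_elementwise_scan(self):
        rng = np.random.default_rng(4)
        y_true = rng.integers(0, 2, 1000)
        y_pred = rng.integers(0, 2, 1000)
        c = confusion(y_true, y_pred)
        tp = fp = tn = fn = 0
        for t, p in zip(y_true, y_pred):
            if t == 1 and p == 1:
                tp += 1
            elif t == 0 and p == 1:
                fp += 1
            elif t == 0 and p == 0:
                tn += 1
            else:
                fn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])
        with pytest.raises(ValueError):
            confusion([1, 2], [1, 0])


class TestMetrics:
    def test_perfect_classifier_all_ones(self):
        m = metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert m == type(m)(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_symmetric_counts_give_chance_metrics(self):
        m = metrics(ConfusionCounts(tp=25, fp=25, tn=25, fn=25))
        assert m.accuracy == 0.5
        assert m.mcc == 0.0
        assert m.f1 == 0.5

    def test_benchmark_scale_counts_direct_arithmetic(self):
        # counts consistent with a 1441-positive / 15938-negative benchmark
        c = ConfusionCounts(tp=779, fn=662, tn=15793, fp=145)
        m = metrics(c)
        assert m.accuracy == pytest.approx((779 + 15793) / 17379)
        assert m.accuracy == pytest.approx(0.9536, abs=5e-4)
        assert m.specificity == pytest.approx(0.9909, abs=5e-4)
        assert m.precision == pytest.approx(0.8431, abs=5e-4)
        assert m.recall == pytest.approx(0.5406, abs=5e-4)
        assert m.f1 == pytest.approx(2 * 779 / (2 * 779 + 145 + 662))
        assert m.mcc == pytest.approx(0.6526, abs=5e-3)

    def test_zero_denominators_return_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.precision == 0.0 and m.recall == 0.0 and m.mcc == 0.0

    @given(
        st.tuples(st.integers(0, 500), st.integers(0, 500),
                  st.integers(0, 500), st.integers(0, 500)).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=100, deadline=None)
    def test_f1_harmonic_mean_identity_and_ranges(self, counts):
        tp, fp, tn, fn = counts
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        for v in (m.accuracy, m.specificity, m.precision, m.recall, m.f1):
            assert 0.0 <= v <= 1.0
        assert -1.0 <= m.mcc <= 1.0
        if m.precision > 0 and m.recall > 0:
            harmonic = 2 * m.precision * m.recall / (m.precision + m.recall)
            assert m.f1 == pytest.approx(harmonic, abs=1e-12)

    def test_mcc_invariant_under_label_swap(self):
        rng = np.random.default_rng(8)
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        m1 = metrics(confusion(y_true, y_pred))
        m2 = metrics(confusion(1 - y_true, 1 - y_pred))
        assert m1.mcc == pytest.approx(m2.mcc, abs=1e-12)


class TestRocAuc:
    def test_scores_equal_labels_gives_auc_one(self):
        _, auc = roc_auc([0, 1, 0, 1], [0.0, 1.0, 0.0, 1.0])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = roc_auc([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3])
        assert auc == 0.5

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]  # both classes guaranteed
        s = np.round(rng.random(50), 2)  # rounding forces some ties
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(mann_whitney_auc(y, s), abs=1e-12)

    def test_score_negation_complements_auc(self):
        rng = np.random.default_rng(7)
        y = np.array([0, 1] * 25)
        s = rng.permutation(50).astype(float)  # tie-free
        _, a1 = roc_auc(y, s)
        _, a2 = roc_auc(y, -s)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestFiveFoldSplit:
    def test_five_samples_singleton_folds(self):
        fa = five_fold_split(5, seed=0)
        sizes = [fa.indices(k).size for k in range(5)]
        assert sizes == [1] * 5

    def test_benchmark_size_fold_balance(self):
        fa = five_fold_split(17379, seed=1)
        sizes = sorted(fa.indices(k).size for k in range(5))
        assert sizes == [3475, 3476, 3476, 3476, 3476]

    @given(st.integers(5, 400), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, n, seed):
        fa = five_fold_split(n, seed=seed)
        all_idx = np.concatenate([fa.indices(k) for k in range(5)])
        assert sorted(all_idx) == list(range(n))
        sizes = [fa.indices(k).size for k in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError):
            five_fold_split(4)


class TestCrossValidate:
    def test_separable_features_high_pooled_accuracy(self):
        scanner, cascade = small_forests(10)
        X, y = make_two_class_features(40, n_features=120, signal=4.0, seed=9)
        from dataclasses import replace

        scanner = replace(scanner, window=50)
        res = cross_validate(X, y, scanner, cascade, n_folds=4, seed=9)
        assert res.pooled.accuracy >= 0.9
        assert res.auc >= 0.9

    def test_pooled_counts_equal_fold_sum(self):
        scanner, cascade = small_forests(6)
        from dataclasses import replace

        scanner = replace(scanner, window=40)
        X, y = make_two_class_features(20, n_features=80, signal=3.0, seed=2)
        res = cross_validate(X, y, scanner, cascade, n_folds=4, seed=2)
        total = res.pooled_counts
        assert total.tp + total.fp + total.tn + total.fn == X.shape[0]

    def test_deterministic_rerun(self):
        scanner, cascade = small_forests(5)
        from dataclasses import replace

        scanner = replace(scanner, window=40)
        X, y = make_two_class_features(15, n_features=60, signal=3.0, seed=3)
        r1 = cross_validate(X, y, scanner, cascade, n_folds=3, seed=3)
        r2 = cross_validate(X, y, scanner, cascade, n_folds=3, seed=3)
        assert r1.pooled == r2.pooled
        assert r1.auc == r2.auc


class TestSvmBaseline:
    def test_default_parameters_match_reference(self):
        import inspect

        sig = inspect.signature(svm_baseline)
        assert sig.parameters["c"].default == 0.3
        assert sig.parameters["g"].default == 1000.0

    def test_memorizes_separable_training_data(self):
        X, y = make_two_class_features(50, n_features=20, signal=5.0, seed=1)
        m, _ = svm_baseline(X, y, X, y)
        assert m.accuracy >= 0.99

    def test_deterministic(self):
        X, y = make_two_class_features(30, n_features=10, signal=1.0, seed=8)
        m1, p1 = svm_baseline(X[:40], y[:40], X[40:], y[40:])
        m2, p2 = svm_baseline(X[:40], y[:40], X[40:], y[40:])
        assert m1 == m2
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError):
            svm_baseline(X, np.ones(10, dtype=int), X, np.ones(10, dtype=int))
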