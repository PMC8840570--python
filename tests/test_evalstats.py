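"""Split schemes, AUC, confusion metrics and the signed-rank comparison."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glcmtex import (
    confusion_metrics,
    make_scheme,
    roc_auc,
    run_protocol,
    wilcoxon_compare,
)


def pair_counting_auc(scores, labels):
    """Brute-force oracle: fraction of (positive, negative) pairs correctly ranked."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def trapezoid_auc(scores, labels):
    """Trapezoidal area under the empirical ROC curve."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    P, N = (labels == 1).sum(), (labels == 0).sum()
    tps, fps = [0], [0]
    tp = fp = 0
    for k in range(len(y)):
        tp += y[k] == 1
        fp += y[k] == 0
        if k == len(y) - 1 or s[k + 1] != s[k]:
            tps.append(tp)
            fps.append(fp)
    tpr = np.asarray(tps) / P
    fpr = np.asarray(fps) / N
    return float(np.trapezoid(tpr, fpr))


class TestScheme:
    def test_two_fold_counts_at_n63(self):
        labels = np.array([0] * 31 + [1] * 32)
        scheme = make_scheme(labels, n_repeats=20, seed=5)
        for train, test in scheme.splits:
            assert train.size == 31 and test.size == 32
            assert (labels[train] == 0).sum() == 15
            assert (labels[train] == 1).sum() == 16
            assert np.intersect1d(train, test).size == 0
            assert np.union1d(train, test).size == 63

    def test_leave_one_out(self):
        labels = np.array([0, 1] * 5)
        scheme = make_scheme(labels, kind="leave-one-out")
        assert scheme.n_repeats == 10
        assert all(test.size == 1 for _, test in scheme.splits)
        assert sorted(t[0] for _, t in scheme.splits) == list(range(10))

    def test_seed_determinism(self):
        labels = np.array([0] * 10 + [1] * 10)
        a = make_scheme(labels, n_repeats=5, seed=9)
        b = make_scheme(labels, n_repeats=5, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a.splits, b.splits):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_scheme(np.zeros(10, int))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_hand_computed_example(self):
        # benign {0.1, 0.4}, malignant {0.3, 0.9}: 3 of 4 pairs correct
        scores = [0.1, 0.4, 0.3, 0.9]
        labels = [0, 0, 1, 1]
        assert roc_auc(scores, labels) == 0.75
        assert pair_counting_auc(scores, labels) == 0.75

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 2000)
        labels[:2] = [0, 1]
        auc = roc_auc(rng.random(2000), labels)
        assert 0.45 < auc < 0.55

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_pair_counting_equals_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(n), 2)  # rounded to create ties
        a = pair_counting_auc(scores, labels)
        b = trapezoid_auc(scores, labels)
        assert abs(a - b) < 1e-12
        assert abs(roc_auc(scores, labels) - a) < 1e-12

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestConfusionMetrics:
    def test_all_correct(self):
        acc, sens, spec = confusion_metrics([0.1, 0.9], [0, 1])
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)

    def test_all_predicted_positive(self):
        _, sens, spec = confusion_metrics([0.9, 0.9], [0, 1])
        assert sens == 1.0 and spec == 0.0

    def test_hand_built_confusion_table(self):
        # TP=13, FN=3, TN=14, FP=2
        labels = np.array([1] * 16 + [0] * 16)
        scores = np.array([0.9] * 13 + [0.1] * 3 + [0.1] * 14 + [0.9] * 2)
        acc, sens, spec = confusion_metrics(scores, labels)
        assert np.isclose(sens, 13 / 16)
        assert np.isclose(spec, 14 / 16)
        assert np.isclose(acc, 27 / 32)


class TestProtocol:
    def test_perfect_feature(self):
        labels = np.tile([0, 1], 15)
        scheme = make_scheme(labels, n_repeats=10, seed=0)

        def fit_score(train, test):
            return labels[test].astype(float)

        report = run_protocol(fit_score, labels, scheme)
        assert report.auc_mean == 1.0 and report.auc_std == 0.0
        assert len(report.auc) == 10

    def test_null_feature_centers_on_half(self):
        rng = np.random.default_rng(1)
        labels = np.tile([0, 1], 20)
        scheme = make_scheme(labels, n_repeats=100, seed=2)

        def fit_score(train, test):
            return rng.random(test.size)

        report = run_protocol(fit_score, labels, scheme)
        assert 0.4 < report.auc_mean < 0.6

    def test_pooled_probabilities_average_repeats(self):
        labels = np.tile([0, 1], 6)
        scheme = make_scheme(labels, n_repeats=30, seed=3)
        report = run_protocol(lambda tr, te: labels[te].astype(float), labels, scheme)
        pooled = report.pooled_probabilities(12)
        assert np.allclose(pooled, labels.astype(float))


class TestWilcoxon:
    def test_constant_shift_is_significant(self):
        rng = np.random.default_rng(4)
        a = rng.random(30)
        assert wilcoxon_compare(a, a + 0.2) < 0.05

    def test_matches_exhaustive_enumeration_at_n6(self):
        """Exact p-value equals brute force over all 2^6 sign assignments."""
        rng = np.random.default_rng(8)
        a = rng.random(6)
        b = a + rng.normal(0, 0.3, 6)
        d = a - b
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_pos = ranks[d > 0].sum()
        w_obs = min(w_pos, ranks.sum() - w_pos)
        count = 0
        for signs in product([0, 1], repeat=6):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if min(w, ranks.sum() - w) <= w_obs:
                count += 1
        expected_p = count / 2 ** 6
        assert np.isclose(wilcoxon_compare(a, b), expected_p)

    def test_null_differences_not_significant(self):
        rng = np.random.default_rng(11)
        a = rng.random(200)
        b = a[rng.permutation(200)]
        assert wilcoxon_compare(a, b) > 0.05

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([1.0, 2.0], [1.0, 2.0])
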