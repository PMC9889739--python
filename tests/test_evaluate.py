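"""ROC analysis, Youden cutoff, classification, group metrics."""

import numpy as np
import pytest

from orbitvae.evaluate import (EvaluationError, GroupMetrics, RocResult,
                               ScoreSet, best_cutoff, classify,
                               confusion_from_group_rates, group_metrics,
                               metrics_from_confusion, roc_analysis)


def _pairwise_auc(scores, labels):
    """All-pairs comparison oracle; ties count one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for a in pos:
        for n in neg:
            if a > n:
                wins += 1.0
            elif a == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def _exhaustive_best_j(scores, labels):
    """Max Youden J over all candidate thresholds (values and midpoints)."""
    pos, neg = scores[labels == 1], scores[labels == 0]
    uniq = np.unique(scores)
    cands = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2,
                            [uniq[0] - 1.0]])
    best = -np.inf
    for t in cands:
        best = max(best, np.mean(pos > t) - np.mean(neg > t))
    return best


class TestRoc:
    def test_perfect_separation(self):
        s = ScoreSet(scores=np.array([1, 2, 3, 10, 11, 12.0]),
                     labels=np.array([0, 0, 0, 1, 1, 1]))
        r = roc_analysis(s)
        assert r.auc == pytest.approx(1.0)
        assert r.best_cutoff == pytest.approx(3.0)  # boundary just above 3

    def test_constant_scores_give_half(self):
        s = ScoreSet(scores=np.full(10, 4.2),
                     labels=np.array([0, 1] * 5))
        assert roc_analysis(s).auc == pytest.approx(0.5)

    def test_auc_matches_pairwise_oracle(self, rng):
        for _ in range(200):
            n0, n1 = rng.integers(3, 12, size=2)
            scores = np.round(rng.random(n0 + n1) * 10, 1)  # induce ties
            labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
            r = roc_analysis(ScoreSet(scores=scores, labels=labels))
            assert r.auc == pytest.approx(
                _pairwise_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_analysis(ScoreSet(scores=np.array([1.0, 2.0]),
                                  labels=np.array([0, 0])))

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[:2] = [0, 1]
        base = roc_analysis(ScoreSet(scores=scores, labels=labels)).auc
        for f in (np.exp, lambda x: x ** 3, lambda x: 5 * x + 2):
            t = roc_analysis(ScoreSet(scores=f(scores), labels=labels)).auc
            assert t == pytest.approx(base, abs=1e-12)


class TestBestCutoff:
    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            n0, n1 = rng.integers(3, 10, size=2)
            scores = np.round(rng.random(n0 + n1) * 5, 1)
            labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
            s = ScoreSet(scores=scores, labels=labels)
            r = roc_analysis(s)
            pos, neg = scores[labels == 1], scores[labels == 0]
            j_at_cutoff = np.mean(pos > r.best_cutoff) - np.mean(neg > r.best_cutoff)
            assert j_at_cutoff == pytest.approx(
                _exhaustive_best_j(scores, labels), abs=1e-12)

    def test_overlapping_example(self):
        scores = np.array([1, 2, 3, 4, 3, 4, 5, 6.0])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        r = roc_analysis(ScoreSet(scores=scores, labels=labels))
        j = (np.mean(scores[4:] > r.best_cutoff) -
             np.mean(scores[:4] > r.best_cutoff))
        assert j == pytest.approx(_exhaustive_best_j(scores, labels))

    def test_ties_break_to_lower_threshold(self):
        # J = 1 for any cutoff in [3, 10); the scan must return 3
        s = ScoreSet(scores=np.array([1, 3, 10, 12.0]),
                     labels=np.array([0, 0, 1, 1]))
        assert best_cutoff(roc_analysis(s)) == pytest.approx(3.0)


class TestClassify:
    def test_strict_inequality_at_cutoff(self):
        out = classify(np.array([1.0, 2.0, 3.0]), cutoff=2.0)
        np.testing.assert_array_equal(out, [0, 0, 1])

    def test_all_below(self):
        np.testing.assert_array_equal(classify(np.array([1.0, 1.5]), 5.0), [0, 0])

    def test_vector_matches_scalar(self, rng):
        scores = rng.random(20)
        vec = classify(scores, 0.5)
        for i, s in enumerate(scores):
            assert vec[i] == int(classify(np.array([s]), 0.5)[0])


class TestGroupMetrics:
    def test_validation_worked_example(self):
        """58 normals at 87.9% and 96 abnormals at 72.9% give the printed
        overall accuracy 78.6% and F1 0.809."""
        tn, fp, fn, tp = confusion_from_group_rates(58, 0.879, 96, 0.729)
        assert (tn, fp, fn, tp) == (51, 7, 26, 70)
        m = metrics_from_confusion(tn, fp, fn, tp)
        assert round(m.normal_group_accuracy * 100, 1) == 87.9
        assert round(m.abnormal_group_accuracy * 100, 1) == 72.9
        assert round(m.overall_accuracy * 100, 1) == 78.6
        assert round(m.f1, 3) == 0.809

    def test_test_split_worked_example(self):
        """24 normals at 79.2% and 11 abnormals at 72.7% give overall 77.1%
        and F1 0.667."""
        tn, fp, fn, tp = confusion_from_group_rates(24, 0.792, 11, 0.727)
        assert (tn, fp, fn, tp) == (19, 5, 3, 8)
        m = metrics_from_confusion(tn, fp, fn, tp)
        assert round(m.overall_accuracy * 100, 1) == 77.1
        assert round(m.f1, 3) == 0.667

    def test_perfect_predictions(self):
        t = np.array([0, 0, 1, 1])
        m = group_metrics(t, t)
        assert m.normal_group_accuracy == 1.0
        assert m.abnormal_group_accuracy == 1.0
        assert m.overall_accuracy == 1.0
        assert m.f1 == 1.0
        assert m.undefined == ()

    def test_missing_class_flags_undefined(self):
        m = group_metrics(np.array([0, 0, 0]), np.array([0, 0, 0]))
        assert "abnormal_group_accuracy" in m.undefined
        assert np.isnan(m.abnormal_group_accuracy)
        assert "f1" in m.undefined
        assert m.normal_group_accuracy == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(EvaluationError):
            group_metrics(np.array([]), np.array([]))
        with pytest.raises(EvaluationError):
            group_metrics(np.array([0, 2]), np.array([0, 1]))

    def test_overall_is_convex_combination_of_group_accuracies(self, rng):
        for _ in range(100):
            n = rng.integers(4, 40)
            t = (rng.random(n) < 0.5).astype(int)
            p = (rng.random(n) < 0.5).astype(int)
            if len(np.unique(t)) < 2:
                continue
            m = group_metrics(t, p)
            w0 = (t == 0).mean()
            combo = (w0 * m.normal_group_accuracy +
                     (1 - w0) * m.abnormal_group_accuracy)
            assert m.overall_accuracy == pytest.approx(combo)

    def test_against_confusion_oracle(self, rng):
        """Rates agree with a from-scratch confusion-matrix computation."""
        for _ in range(1000):
            n = int(rng.integers(2, 25))
            t = (rng.random(n) < 0.5).astype(int)
            p = (rng.random(n) < 0.5).astype(int)
            m = group_metrics(t, p)
            tn = sum(1 for a, b in zip(t, p) if a == 0 and b == 0)
            fp = sum(1 for a, b in zip(t, p) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(t, p) if a == 1 and b == 0)
            tp = sum(1 for a, b in zip(t, p) if a == 1 and b == 1)
            assert (m.tn, m.fp, m.fn, m.tp) == (tn, fp, fn, tp)
            if tn + fp:
                assert m.normal_group_accuracy == pytest.approx(tn / (tn + fp))
            if tp + fn:
                assert m.abnormal_group_accuracy == pytest.approx(tp / (tp + fn))
            assert m.overall_accuracy == pytest.approx((tn + tp) / n)
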