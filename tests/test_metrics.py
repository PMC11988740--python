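"""Confusion metrics, ROC/AUC and Youden thresholding against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammowatch.metrics import (
    ConfusionCounts,
    auc,
    binarize,
    confusion,
    evaluate_scores,
    label_from_birads,
    metric_set,
    reconstruct_confusion,
    roc,
    round_half_away,
    youden_threshold,
)

from conftest import pairwise_auc

# score values drawn from a coarse grid so ties occur often
score_grid = st.sampled_from([i / 10 for i in range(11)])


def small_instances():
    return st.tuples(
        st.lists(score_grid, min_size=1, max_size=10),  # positives
        st.lists(score_grid, min_size=1, max_size=10),  # negatives
    )


class TestBinarize:
    @pytest.mark.parametrize(
        "score, threshold, expected",
        [
            (0.50, 0.50, True),   # inclusive boundary: equal score is positive
            (0.49, 0.50, False),
            (0.0, 0.0, True),     # threshold 0 calls everything positive
            (1.0, 1.0, True),
        ],
    )
    def test_threshold_rule(self, score, threshold, expected):
        assert binarize([score], threshold)[0] == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            binarize([1.5], 0.5)
        with pytest.raises(ValueError):
            binarize([0.5], -0.1)


class TestBiradsLabel:
    @pytest.mark.parametrize(
        "birads, label",
        [(1, 0), (2, 0), (3, 1), (4, 1), (5, 1), (6, 1)],
    )
    def test_mapping(self, birads, label):
        assert label_from_birads(birads) == label

    def test_missing_is_undefined(self):
        assert label_from_birads(None) is None
        assert label_from_birads(float("nan")) is None

    @pytest.mark.parametrize("bad", [0, 7, -1])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            label_from_birads(bad)


class TestConfusion:
    def test_one_of_each_outcome(self):
        c = confusion([1, 0, 1, 0], [1, 0, 0, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_all_correct_has_no_errors(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert c.fp == 0 and c.fn == 0

    def test_all_positive_calls(self):
        calls = [1] * 10
        labels = [1] * 5 + [0] * 5
        c = confusion(calls, labels)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 5, 0, 0)

    def test_partition(self):
        c = confusion([1, 0, 1], [0, 0, 1])
        assert c.total == 3

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])
        with pytest.raises(ValueError):
            confusion([], [])
        with pytest.raises(ValueError):
            confusion([1], [2])


class TestMetricSet:
    def test_calibration_table_first_test(self):
        # counts reconstructed from sens 0.62 / spec 0.84 at 50/50, n=100
        m = metric_set(ConfusionCounts(tp=31, tn=42, fp=8, fn=19)).rounded(2)
        assert m["accuracy"] == 0.73
        assert m["sensitivity"] == 0.62
        assert m["specificity"] == 0.84
        assert m["precision"] == 0.79
        assert m["f1"] == 0.70

    def test_calibration_table_second_test(self):
        m = metric_set(ConfusionCounts(tp=34, tn=42, fp=8, fn=16)).rounded(2)
        assert m["accuracy"] == 0.76
        assert m["precision"] == 0.81
        assert m["f1"] == 0.74

    def test_zero_denominators_are_undefined_not_zero(self):
        m = metric_set(ConfusionCounts(tp=5, tn=0, fp=0, fn=0))
        assert m.specificity is None
        assert m.accuracy == 1.0 and m.sensitivity == 1.0 and m.f1 == 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metric_set(ConfusionCounts(0, 0, 0, 0))


class TestROC:
    def test_perfectly_separated_curve(self):
        scores = [0.7, 0.9, 0.2, 0.6]
        labels = [1, 1, 0, 0]
        curve = roc(scores, labels)
        pts = {(f, t) for f, t, _ in curve.points()}
        assert {(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)} <= pts
        assert auc(curve) == 1.0

    def test_identical_scores_give_diagonal(self):
        curve = roc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert curve.points() == [(0.0, 0.0, np.inf), (1.0, 1.0, 0.5)]
        assert auc(curve) == pytest.approx(0.5)

    def test_single_tied_pair_scores_half(self):
        assert auc(roc([0.4, 0.4], [1, 0])) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([0.2, 0.8], [1, 1])

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(small_instances())
    def test_auc_equals_pairwise_concordance(self, instance):
        pos, neg = instance
        scores = np.array(pos + neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        assert auc(roc(scores, labels)) == pytest.approx(pairwise_auc(pos, neg))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(small_instances())
    def test_auc_matches_sklearn(self, instance):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        pos, neg = instance
        scores = np.array(pos + neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        assert auc(roc(scores, labels)) == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores)
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(small_instances())
    def test_auc_invariant_under_increasing_transform(self, instance):
        pos, neg = instance
        scores = np.array(pos + neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        # x^2 is strictly increasing on [0, 1]
        assert auc(roc(scores**2, labels)) == pytest.approx(auc(roc(scores, labels)))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(small_instances())
    def test_label_swap_complements_auc(self, instance):
        pos, neg = instance
        scores = np.array(pos + neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        assert auc(roc(scores, 1 - labels)) == pytest.approx(
            1.0 - auc(roc(scores, labels))
        )


def brute_force_youden(scores, labels):
    """Exhaustive search over the achievable thresholds (incl. the sentinel)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = np.sum(labels == 1)
    n_neg = np.sum(labels == 0)
    candidates = [(np.inf, 0.0)]  # nothing called positive: J = 0
    for t in np.unique(scores):
        calls = scores >= t
        sens = np.sum(calls & (labels == 1)) / n_pos
        spec = np.sum(~calls & (labels == 0)) / n_neg
        candidates.append((float(t), float(sens + spec - 1.0)))
    j_best = max(j for _, j in candidates)
    t_best = min(t for t, j in candidates if j >= j_best - 1e-12)
    return t_best, j_best


class TestYouden:
    def test_perfect_separation(self):
        curve = roc([0.7, 0.9, 0.2, 0.6], [1, 1, 0, 0])
        t, j = youden_threshold(curve)
        assert t == 0.7 and j == pytest.approx(1.0)

    def test_tied_scores_return_smallest_threshold(self):
        curve = roc([0.5, 0.5], [1, 0])
        t, j = youden_threshold(curve)
        assert j == pytest.approx(0.0)
        assert t == 0.5  # smaller than the sentinel, also J = 0

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(small_instances())
    def test_agrees_with_brute_force(self, instance):
        pos, neg = instance
        scores = np.array(pos + neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        t_ref, j_ref = brute_force_youden(scores, labels)
        t, j = youden_threshold(roc(scores, labels))
        assert j == pytest.approx(j_ref)
        assert t == pytest.approx(t_ref)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(small_instances())
    def test_roc_point_reproduces_metrics_at_threshold(self, instance):
        pos, neg = instance
        scores = np.array(pos + neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        curve = roc(scores, labels)
        for fpr, tpr, t in curve.points():
            if not np.isfinite(t):
                continue
            m = metric_set(confusion(binarize(scores, t), labels))
            assert m.sensitivity == pytest.approx(tpr)
            assert m.specificity == pytest.approx(1.0 - fpr)


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "sens, spec, n_pos, n_neg, expected",
        [
            (0.62, 0.84, 50, 50, (31, 42, 8, 19)),
            (1.0, 1.0, 7, 9, (7, 9, 0, 0)),
            (0.92, 0.78, 50, 50, (46, 39, 11, 4)),
        ],
    )
    def test_examples(self, sens, spec, n_pos, n_neg, expected):
        c = reconstruct_confusion(sens, spec, n_pos, n_neg)
        assert (c.tp, c.tn, c.fp, c.fn) == expected

    def test_rejects_rates_outside_unit_interval(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(1.2, 0.5, 10, 10)


class TestRounding:
    @pytest.mark.parametrize(
        "x, decimals, expected",
        [(2.5, 0, 3.0), (-2.5, 0, -3.0), (-13.888, 0, -14.0), (13.41, 1, 13.4)],
    )
    def test_half_away_from_zero(self, x, decimals, expected):
        assert round_half_away(x, decimals) == expected


def test_evaluate_scores_end_to_end():
    scores = [0.9, 0.8, 0.7, 0.4, 0.3, 0.2]
    labels = [1, 1, 0, 1, 0, 0]
    ev = evaluate_scores(scores, labels)
    t_ref, j_ref = brute_force_youden(np.array(scores), np.array(labels))
    assert ev.threshold == pytest.approx(t_ref)
    assert ev.metrics.auc == pytest.approx(pairwise_auc([0.9, 0.8, 0.4], [0.7, 0.3, 0.2]))
    assert ev.counts.total == 6
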