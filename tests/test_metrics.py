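"""Metric correctness: hand-computed examples, independent oracles
(full-matrix DP, edlib, exhaustive matching, scikit-learn) and the
invariants that make the segmental scores meaningful."""

import edlib
import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import confusion_matrix as sk_confusion

from surgseg.metrics import (EvalReport, aggregate_reports, confusion_matrix,
                             edit_score, evaluate, f1_at_k, frame_accuracy,
                             labels_from_segments, levenshtein,
                             segments_from_labels)

from oracles import (exhaustive_f1, exhaustive_tp, greedy_tp,
                     levenshtein_full_dp, random_segment_list)

label_arrays = st.lists(st.integers(0, 4), min_size=1, max_size=60).map(np.array)
class_seqs = st.lists(st.integers(0, 3), min_size=0, max_size=12)


# -- frame level ------------------------------------------------------------

def test_frame_accuracy_examples():
    assert frame_accuracy([0, 0, 1, 1], [0, 1, 1, 1]) == 75.0
    assert frame_accuracy([1, 2, 3], [1, 2, 3]) == 100.0
    assert frame_accuracy([0, 1], [1, 0]) == 0.0
    # unannotated ground-truth frames are excluded
    assert frame_accuracy([0, 9, 9, 1], [0, -1, -1, 1]) == 100.0
    with pytest.raises(ValueError):
        frame_accuracy([0, 1], [0, 1, 2])


def test_confusion_matrix_against_sklearn(rng):
    gt = rng.integers(0, 5, 300)
    pred = rng.integers(0, 5, 300)
    cm = confusion_matrix(pred, gt, 5)
    np.testing.assert_array_equal(cm, sk_confusion(gt, pred, labels=range(5)))
    assert cm.sum() == 300
    # trace/T relation to frame accuracy
    assert frame_accuracy(pred, gt) == pytest.approx(100.0 * cm.trace() / 300)


# -- run-length form --------------------------------------------------------

def test_segments_examples():
    assert segments_from_labels([0, 0, 1, 1, 1, 0]) == [(0, 2, 0), (2, 5, 1), (5, 6, 0)]
    assert segments_from_labels([3] * 7) == [(0, 7, 3)]


@given(label_arrays)
def test_segments_roundtrip(labels):
    segs = segments_from_labels(labels)
    np.testing.assert_array_equal(labels_from_segments(segs, len(labels)), labels)
    # maximal runs: adjacent segments have distinct classes
    assert all(a[2] != b[2] for a, b in zip(segs, segs[1:]))


# -- Levenshtein / edit score ----------------------------------------------

def test_levenshtein_examples():
    assert levenshtein("", "ABC") == 3
    assert levenshtein("AB", "AB") == 0
    assert levenshtein("kitten", "sitting") == 3


@given(class_seqs, class_seqs)
def test_levenshtein_against_independent_oracles(a, b):
    d = levenshtein(a, b)
    assert d == levenshtein_full_dp(a, b)
    # edlib on a character encoding of the class sequences
    ea = "".join(chr(65 + c) for c in a)
    eb = "".join(chr(65 + c) for c in b)
    assert d == edlib.align(ea, eb, task="distance")["editDistance"]
    assert d == levenshtein(b, a)
    assert (d == 0) == (list(a) == list(b))


@given(class_seqs, class_seqs, class_seqs)
def test_levenshtein_triangle_inequality(a, b, c):
    assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


def _as_segments(classes):
    return [(i, i + 1, c) for i, c in enumerate(classes)]


def test_edit_score_examples():
    assert edit_score(_as_segments([1, 2, 1]), _as_segments([1, 2, 1])) == 100.0
    assert edit_score(_as_segments([0]), _as_segments([0, 1])) == 50.0
    assert edit_score(_as_segments([0, 1, 0]), _as_segments([2, 3, 2])) == 0.0
    assert edit_score([], []) == 100.0


@given(class_seqs, class_seqs)
def test_edit_score_symmetric_and_bounded(a, b):
    s = edit_score(_as_segments(a), _as_segments(b))
    assert s == edit_score(_as_segments(b), _as_segments(a))
    assert 0.0 <= s <= 100.0


def test_edit_score_penalizes_over_segmentation(rng):
    """A prediction shattered into m segments against n ground-truth
    segments can never score above 100*min(m,n)/max(m,n), because the
    distance is at least the length difference; and a single inserted
    segment moves the distance by at most one."""
    for _ in range(300):
        gt = [c for _, _, c in random_segment_list(rng, max_segments=8)]
        pred = [c for _, _, c in random_segment_list(rng, max_segments=8)]
        m, n = len(pred), len(gt)
        score = edit_score(_as_segments(pred), _as_segments(gt))
        assert score <= 100.0 * min(m, n) / max(m, n) + 1e-9
        i = int(rng.integers(0, m))
        split = pred[:i] + [pred[i]] + pred[i:]
        assert abs(levenshtein(split, gt) - levenshtein(pred, gt)) <= 1


# -- segmental F1 -----------------------------------------------------------

def test_f1_single_pair_iou_thresholds():
    pred = [(0, 10, 3)]
    gt = [(0, 25, 3)]  # IoU = 10/25 = 0.4
    assert f1_at_k(pred, gt, 10) == 100.0
    assert f1_at_k(pred, gt, 25) == 100.0
    assert f1_at_k(pred, gt, 50) == 0.0


def test_f1_perfect_prediction(rng):
    segs = random_segment_list(rng, max_segments=8)
    for k in (10, 25, 50):
        assert f1_at_k(segs, segs, k) == 100.0


def test_f1_monotone_in_threshold(rng):
    for _ in range(500):
        a = random_segment_list(rng)
        b = random_segment_list(rng)
        f10, f25, f50 = (f1_at_k(a, b, k) for k in (10, 25, 50))
        assert f50 <= f25 + 1e-9 and f25 <= f10 + 1e-9


def test_greedy_matching_bounded_by_optimal(rng):
    """Greedy first-match can never beat the enumerated optimal matching,
    and agrees with it on the overwhelming majority of random pairs."""
    agree = 0
    total = 0
    for _ in range(300):
        a = random_segment_list(rng)
        b = random_segment_list(rng)
        for k in (10, 25, 50):
            g, o = greedy_tp(a, b, k), exhaustive_tp(a, b, k)
            assert g <= o
            total += 1
            agree += g == o
    assert agree / total > 0.99


def test_greedy_suboptimal_counterexample():
    """A frozen case where greedy max-IoU matching is strictly suboptimal:
    the first long prediction claims the ground-truth segment that the
    only other same-class prediction could have matched."""
    pred = [(0, 9, 2), (9, 13, 0), (13, 30, 2), (30, 40, 1)]
    gt = [(0, 1, 2), (1, 6, 1), (6, 24, 2), (24, 33, 1), (33, 45, 2)]
    # greedy lets pred[0] claim gt[2] (IoU 0.125 beats gt[0]'s 0.111), which
    # starves pred[2]; the optimal assignment matches pred[0]->gt[0],
    # pred[2]->gt[2], pred[3]->gt[3]
    assert greedy_tp(pred, gt, 10) == 2
    assert exhaustive_tp(pred, gt, 10) == 3
    assert f1_at_k(pred, gt, 10) == pytest.approx(100 * 2 * (2 / 4) * (2 / 5) / (2 / 4 + 2 / 5))
    assert f1_at_k(pred, gt, 10) < exhaustive_f1(pred, gt, 10)


# -- report bundling --------------------------------------------------------

def test_evaluate_perfect_prediction(rng):
    gt = rng.integers(0, 4, 120)
    rep = evaluate(gt, gt, 4)
    assert rep.frame_accuracy == 100.0
    assert rep.edit_score == 100.0
    assert set(rep.f1_at) == {10, 25, 50}
    assert all(v == 100.0 for v in rep.f1_at.values())
    assert np.all(rep.confusion == np.diag(np.bincount(gt, minlength=4)))


def test_evaluate_invariant_to_class_relabelling(rng):
    gt = rng.integers(0, 4, 150)
    pred = rng.integers(0, 4, 150)
    perm = np.array([2, 0, 3, 1])
    a = evaluate(pred, gt, 4)
    b = evaluate(perm[pred], perm[gt], 4)
    assert a.frame_accuracy == pytest.approx(b.frame_accuracy)
    assert a.edit_score == pytest.approx(b.edit_score)
    for k in (10, 25, 50):
        assert a.f1_at[k] == pytest.approx(b.f1_at[k])


def test_aggregate_reports_is_unweighted_mean():
    r1 = EvalReport(80.0, 60.0, {10: 50.0}, np.eye(2, dtype=int), 100.0)
    r2 = EvalReport(100.0, 100.0, {10: 100.0}, np.eye(2, dtype=int), 50.0)
    agg = aggregate_reports([r1, r2])
    assert agg.frame_accuracy == 90.0
    assert agg.edit_score == 80.0
    assert agg.f1_at[10] == 75.0
    assert agg.skill_accuracy == 75.0
    np.testing.assert_array_equal(agg.confusion, 2 * np.eye(2, dtype=int))
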