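"""Frame-wise and segmental evaluation of gesture label sequences.

Frame-wise accuracy ignores temporal structure, so two predictions with the
same number of correct frames score identically even if one of them is
shattered into many spurious segments.  The segmental metrics penalize such
over-segmentation: the edit score compares the *order* of segment classes
through a normalized Levenshtein distance, and F1@k scores segments as true
positives when their temporal intersection-over-union with a same-class
ground-truth segment exceeds k percent.

Frames labelled ``-1`` in the ground truth are treated as unannotated
(e.g. lead-in/lead-out frames outside any transcript segment) and are
excluded from every metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Segment",
    "segments_from_labels",
    "labels_from_segments",
    "frame_accuracy",
    "levenshtein",
    "edit_score",
    "f1_at_k",
    "confusion_matrix",
    "EvalReport",
    "evaluate",
    "aggregate_reports",
]

UNLABELLED = -1

#: A segment is (start, end, class) with a 0-based half-open [start, end).
Segment = tuple[int, int, int]


def segments_from_labels(labels) -> list[Segment]:
    """Run-length encode a label sequence into maximal constant segments."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size < 1:
        raise ValueError("labels must be a non-empty 1-D sequence")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    return [(int(s), int(e), int(labels[s])) for s, e in zip(bounds[:-1], bounds[1:])]


def labels_from_segments(segments: list[Segment], length: int | None = None,
                         fill: int = UNLABELLED) -> np.ndarray:
    """Expand segments back to a per-frame label vector (inverse of RLE)."""
    if length is None:
        length = max((e for _, e, _ in segments), default=0)
    labels = np.full(length, fill, dtype=int)
    for s, e, c in segments:
        labels[s:e] = c
    return labels


def _masked(pred, gt):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape or pred.ndim != 1:
        raise ValueError("pred and gt must be 1-D sequences of equal length")
    keep = gt != UNLABELLED
    if not keep.any():
        raise ValueError("ground truth has no annotated frames")
    return pred[keep], gt[keep]


def frame_accuracy(pred, gt) -> float:
    """Percentage of annotated frames classified correctly."""
    pred, gt = _masked(pred, gt)
    return 100.0 * float(np.mean(pred == gt))


def levenshtein(a, b) -> int:
    """Minimum number of insertions, deletions and substitutions turning a into b."""
    a, b = list(a), list(b)
    if len(a) < len(b):
        a, b = b, a
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = np.empty_like(prev)
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev[-1])


def _class_sequence(segments: list[Segment]) -> list[int]:
    return [c for _, _, c in segments]


def edit_score(pred_segments: list[Segment], gt_segments: list[Segment]) -> float:
    """Normalized Levenshtein similarity of the two segment class orders.

    ``100 * (1 - D / max(len(pred), len(gt)))`` clamped at 0, where D is the
    Levenshtein distance between the class sequences.  Two empty lists are
    identical by convention (score 100).
    """
    a, b = _class_sequence(pred_segments), _class_sequence(gt_segments)
    denom = max(len(a), len(b))
    if denom == 0:
        return 100.0
    return max(0.0, 100.0 * (1.0 - levenshtein(a, b) / denom))


def _iou(a: Segment, b: Segment) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union


def f1_at_k(pred_segments: list[Segment], gt_segments: list[Segment],
            k: float) -> float:
    """Segmental F1 at IoU threshold k (percent).

    Predicted segments are scanned in temporal order; each claims the
    unmatched same-class ground-truth segment of highest IoU, and counts as
    a true positive when that IoU strictly exceeds k/100.  Ground-truth
    segments left unmatched are false negatives.  F1 = 2PR/(P+R), defined
    as 0 when there are no segments to match on either side, and 100 when
    both sides are empty.
    """
    if not 0 < k < 100:
        raise ValueError("k must be in (0, 100)")
    if not pred_segments and not gt_segments:
        return 100.0
    thresh = k / 100.0
    matched = [False] * len(gt_segments)
    tp = fp = 0
    for p in pred_segments:
        best, best_j = 0.0, -1
        for j, g in enumerate(gt_segments):
            if g[2] != p[2] or matched[j]:
                continue
            iou = _iou(p, g)
            if iou > best:
                best, best_j = iou, j
        if best_j >= 0 and best > thresh:
            matched[best_j] = True
            tp += 1
        else:
            fp += 1
    fn = len(gt_segments) - tp
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 100.0 * 2 * precision * recall / (precision + recall)


def confusion_matrix(pred, gt, n_classes: int) -> np.ndarray:
    """Counts with ground truth on rows, predictions on columns."""
    pred, gt = _masked(pred, gt)
    if np.any(gt >= n_classes) or np.any(pred >= n_classes) or np.any(pred < 0):
        raise ValueError("labels out of range for the requested class count")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (gt, pred), 1)
    return cm


@dataclass
class EvalReport:
    """All metrics of one evaluation run (percentages on a 0-100 scale)."""

    frame_accuracy: float
    edit_score: float
    f1_at: dict[int, float]
    confusion: np.ndarray
    skill_accuracy: float | None = None

    def to_dict(self) -> dict[str, float]:
        d = {"frame_accuracy": self.frame_accuracy, "edit_score": self.edit_score}
        d.update({f"f1@{k}": v for k, v in sorted(self.f1_at.items())})
        if self.skill_accuracy is not None:
            d["skill_accuracy"] = self.skill_accuracy
        return d


F1_THRESHOLDS = (10, 25, 50)


def evaluate(pred, gt, n_classes: int,
             thresholds=F1_THRESHOLDS) -> EvalReport:
    """Bundle frame accuracy, edit score, F1@k and the confusion matrix.

    Unannotated ground-truth frames are dropped before both the frame-wise
    and the segmental metrics (the remaining frames are concatenated).
    """
    pred_m, gt_m = _masked(pred, gt)
    ps, gs = segments_from_labels(pred_m), segments_from_labels(gt_m)
    return EvalReport(
        frame_accuracy=frame_accuracy(pred, gt),
        edit_score=edit_score(ps, gs),
        f1_at={k: f1_at_k(ps, gs, k) for k in thresholds},
        confusion=confusion_matrix(pred, gt, n_classes),
    )


def aggregate_reports(reports: list[EvalReport]) -> EvalReport:
    """Unweighted mean over folds; confusion matrices are summed."""
    if not reports:
        raise ValueError("no reports to aggregate")
    keys = reports[0].f1_at.keys()
    skills = [r.skill_accuracy for r in reports if r.skill_accuracy is not None]
    return EvalReport(
        frame_accuracy=float(np.mean([r.frame_accuracy for r in reports])),
        edit_score=float(np.mean([r.edit_score for r in reports])),
        f1_at={k: float(np.mean([r.f1_at[k] for r in reports])) for k in keys},
        confusion=np.sum([r.confusion for r in reports], axis=0),
        skill_accuracy=float(np.mean(skills)) if skills else None,
    )
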