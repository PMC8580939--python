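"""Independent oracles used by the test suite.

These deliberately re-derive quantities through different algorithms than
the package (full-matrix DP, exhaustive enumeration, explicit loops) so
that agreement is meaningful.
"""

from functools import lru_cache

import numpy as np


def levenshtein_full_dp(a, b) -> int:
    """Textbook full-matrix edit-distance DP (independent of the package's
    rolling-row implementation)."""
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1), dtype=int)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(D[i - 1, j] + 1,
                          D[i, j - 1] + 1,
                          D[i - 1, j - 1] + (a[i - 1] != b[j - 1]))
    return int(D[n, m])


def _iou(a, b) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / (max(a[1], b[1]) - min(a[0], b[0]))


def exhaustive_f1(pred, gt, k) -> float:
    """F1@k under the *optimal* injective same-class matching, found by
    enumerating all matchings (bitmask over ground-truth segments)."""
    thresh = k / 100.0
    cand = [[j for j, g in enumerate(gt) if g[2] == p[2] and _iou(p, g) > thresh]
            for p in pred]

    @lru_cache(maxsize=None)
    def best(i, used):
        if i == len(pred):
            return 0
        b = best(i + 1, used)
        for j in cand[i]:
            if not used & (1 << j):
                b = max(b, 1 + best(i + 1, used | (1 << j)))
        return b

    tp = best(0, 0)
    best.cache_clear()
    if not pred and not gt:
        return 100.0
    if tp == 0:
        return 0.0
    p = tp / len(pred)
    r = tp / len(gt)
    return 100.0 * 2 * p * r / (p + r)


def exhaustive_tp(pred, gt, k) -> int:
    """Optimal true-positive count (same enumeration as exhaustive_f1)."""
    thresh = k / 100.0
    cand = [[j for j, g in enumerate(gt) if g[2] == p[2] and _iou(p, g) > thresh]
            for p in pred]

    @lru_cache(maxsize=None)
    def best(i, used):
        if i == len(pred):
            return 0
        b = best(i + 1, used)
        for j in cand[i]:
            if not used & (1 << j):
                b = max(b, 1 + best(i + 1, used | (1 << j)))
        return b

    out = best(0, 0)
    best.cache_clear()
    return out


def greedy_tp(pred, gt, k) -> int:
    """True-positive count of the package's greedy matching rule, recomputed
    here with explicit loops."""
    thresh = k / 100.0
    matched = [False] * len(gt)
    tp = 0
    for p in pred:
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gt):
            if g[2] != p[2] or matched[j]:
                continue
            iou = _iou(p, g)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou > thresh:
            matched[best_j] = True
            tp += 1
    return tp


def random_segment_list(rng, max_segments=5, n_classes=3, max_duration=19):
    """A valid segment list: contiguous, adjacent classes distinct."""
    n = int(rng.integers(1, max_segments + 1))
    t, out, prev = 0, [], -1
    for _ in range(n):
        c = int(rng.integers(0, n_classes))
        while c == prev:
            c = int(rng.integers(0, n_classes))
        d = int(rng.integers(1, max_duration + 1))
        out.append((t, t + d, c))
        t += d
        prev = c
    return out


def attention_loops(Q, K, V):
    """Scaled dot-product attention with explicit per-element loops."""
    n, d_k = Q.shape
    out = np.zeros((n, V.shape[1]))
    for i in range(n):
        scores = np.array([sum(Q[i, d] * K[j, d] for d in range(d_k)) / np.sqrt(d_k)
                           for j in range(n)])
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        for j in range(n):
            out[i] += w[j] * V[j]
    return out


def finite_difference_grad(f, arr, indices, eps=1e-6):
    """Central-difference gradient of scalar f() wrt arr at flat indices."""
    flat = arr.ravel()
    out = {}
    for i in indices:
        orig = flat[i]
        flat[i] = orig + eps
        lp = f()
        flat[i] = orig - eps
        lm = f()
        flat[i] = orig
        out[i] = (lp - lm) / (2 * eps)
    return out
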