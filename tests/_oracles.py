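"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plainly as possible (explicit loops over
all candidate splits / pairs) and deliberately shares no code with the
package under test.
"""

from __future__ import annotations

import math

import numpy as np


def brute_rft(x, y, min_segment: int = 2) -> float:
    """Exhaustive two-segment pooled RMSE over midpoint thresholds."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    uniq = np.unique(x)
    best = float(np.std(y))  # single-segment fallback
    found = False
    for a, b in zip(uniq[:-1], uniq[1:]):
        t = (a + b) / 2.0
        left = y[x <= t]
        right = y[x > t]
        if len(left) < min_segment or len(right) < min_segment:
            continue
        sse = np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2)
        loss = math.sqrt(sse / n)
        if not found or loss < best:
            best, found = loss, True
    return best


def _entropy2(labels) -> float:
    labels = np.asarray(labels)
    if len(labels) == 0:
        return 0.0
    p = labels.mean()
    h = 0.0
    for q in (p, 1 - p):
        if q > 0:
            h -= q * math.log2(q)
    return h


def brute_dft(x, labels, min_segment: int = 2) -> float:
    """Exhaustive two-segment weighted entropy over midpoint thresholds."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n = len(x)
    uniq = np.unique(x)
    best = _entropy2(labels)
    found = False
    for a, b in zip(uniq[:-1], uniq[1:]):
        t = (a + b) / 2.0
        li = labels[x <= t]
        ri = labels[x > t]
        if len(li) < min_segment or len(ri) < min_segment:
            continue
        loss = (len(li) * _entropy2(li) + len(ri) * _entropy2(ri)) / n
        if not found or loss < best:
            best, found = loss, True
    return best


def pair_count_auc(labels, scores) -> float:
    """AUC by direct enumeration of all positive-negative pairs."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def confusion_counts(labels, scores, threshold) -> dict:
    """Direct tabulation of the 2x2 confusion matrix."""
    labels = np.asarray(labels).astype(int)
    pred = (np.asarray(scores, dtype=float) > threshold).astype(int)
    out = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for t, p in zip(labels, pred):
        key = {(1, 1): "tp", (0, 0): "tn", (0, 1): "fp", (1, 0): "fn"}[(t, p)]
        out[key] += 1
    return out
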