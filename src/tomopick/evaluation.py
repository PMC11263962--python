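"""Detection scoring: distance-based matching and precision/recall/F1.

Predictions are matched one-to-one to ground-truth positions greedily by
ascending pair distance among all pairs within a threshold (default: the
particle radius in voxels). Greedy nearest-pair matching is the standard
choice in the picking literature; one-to-one matching prevents a single
prediction from claiming several truths in crowded fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["MatchResult", "match_detections", "precision_recall_f1"]

logger = logging.getLogger(__name__)

Position = Sequence[float]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (pred, truth, dist)
    dist_threshold: float = 0.0


def match_detections(
    pred: Sequence[Position], truth: Sequence[Position], dist_threshold: float
) -> MatchResult:
    """Greedy one-to-one matching by ascending pair distance.

    Ties in distance are broken by prediction index then truth index, so the
    result is deterministic. Unmatched predictions are false positives,
    unmatched truths false negatives.
    """
    if dist_threshold <= 0:
        raise ValueError("dist_threshold must be > 0")
    p = np.asarray(pred, dtype=float).reshape(len(pred), -1) if len(pred) else np.empty((0, 3))
    t = np.asarray(truth, dtype=float).reshape(len(truth), -1) if len(truth) else np.empty((0, 3))
    pairs: list[tuple[float, int, int]] = []
    if len(p) and len(t):
        d = np.linalg.norm(p[:, None, :] - t[None, :, :], axis=2)
        for i, j in np.argwhere(d <= dist_threshold):
            pairs.append((float(d[i, j]), int(i), int(j)))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matched: list[tuple[int, int, float]] = []
    for dist, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matched.append((i, j, dist))
    tp = len(matched)
    return MatchResult(
        tp=tp,
        fp=len(p) - tp,
        fn=len(t) - tp,
        pairs=matched,
        dist_threshold=float(dist_threshold),
    )


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """Precision, recall and F1 from a match result.

    The degenerate all-zero case (no predictions, no truths) returns
    (1, 1, 1) — a vacuously perfect detection — with a warning; zero
    denominators otherwise yield 0.
    """
    if m.tp == 0 and m.fp == 0 and m.fn == 0:
        logger.warning("precision_recall_f1: empty prediction and truth sets")
        return (1.0, 1.0, 1.0)
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 0.0
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return (precision, recall, f1)
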