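"""Consensus score fusion and challenge-style evaluation.

Detections are matched to ground-truth mitoses by greedy nearest-first
one-to-one assignment within 30 px (Euclidean, inclusive).  Telophase
figures — two daughter lobes of one dividing cell — are merged to a single
target before matching so the pair counts once; surplus predictions that
fall within the radius of an already-matched target are suppressed (neither
TP nor FP) by default, since each of them does "lie within 30 pixels" of a
true mitosis.  Precision, recall and F-score follow the standard challenge
definitions, with zero-division guarded to 0; the PR curve sweeps the unique
confidence values and its area uses the step-wise (rectangle) rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MatchResult",
    "MetricsReport",
    "fuse_scores",
    "match_detections",
    "compute_metrics",
    "f_score",
    "pr_curve",
]

DEFAULT_MATCH_DIST = 30.0


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairing: list  # [(target_idx, pred_idx)]
    suppressed: list = field(default_factory=list)  # pred indices neither TP nor FP


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f_score: float
    pr_points: list | None = None  # [(recall, precision)] ordered by threshold
    pr_auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
        }
        if self.pr_points is not None:
            d["pr_points"] = [list(p) for p in self.pr_points]
        if self.pr_auc is not None:
            d["pr_auc"] = self.pr_auc
        return d


def fuse_scores(per_classifier: Mapping[str, Sequence[float]], priority: Sequence[str] | None = None):
    """Highest-confidence score fusion across classifiers.

    ``per_classifier`` maps classifier name -> aligned per-patch mitosis
    probabilities.  For each patch the classifier whose class-confidence
    max(p, 1-p) is largest dictates the class; ties resolve by ``priority``
    (default: mapping order).  Returns ``(is_mitosis, fused_confidence,
    fused_p_mitosis)`` arrays; ``fused_confidence`` is the winning
    class-confidence and ``fused_p_mitosis`` the winner's mitosis
    probability.
    """
    names = list(priority) if priority is not None else list(per_classifier)
    if len(names) < 2:
        raise ValueError("score fusion needs at least two classifiers")
    arrays = []
    n = None
    for name in names:
        a = np.asarray(per_classifier[name], dtype=float)
        if n is None:
            n = len(a)
        elif len(a) != n:
            raise ValueError("per-classifier score vectors are misaligned")
        arrays.append(a)
    probs = np.stack(arrays, axis=0)  # (C, N)
    conf = np.maximum(probs, 1.0 - probs)
    winner = conf.argmax(axis=0)  # argmax takes the first max -> priority order
    idx = np.arange(n)
    p_win = probs[winner, idx]
    return p_win > 0.5, conf[winner, idx], p_win


def _merge_targets(gt_centroids: np.ndarray, groups):
    """Group gt centroids into targets; a target is the list of its member points."""
    gt = np.asarray(gt_centroids, dtype=float).reshape(-1, 2)
    if groups is None:
        return [[i] for i in range(len(gt))], gt
    groups = np.asarray(groups)
    targets = []
    for g in dict.fromkeys(groups.tolist()):  # preserve first-seen order
        targets.append(np.flatnonzero(groups == g).tolist())
    return targets, gt


def match_detections(
    pred_points: Sequence[tuple],
    scores: Sequence[float] | None,
    gt_centroids: Sequence[tuple],
    max_dist: float = DEFAULT_MATCH_DIST,
    groups: Sequence | None = None,
    surplus: str = "suppress",
) -> MatchResult:
    """Greedy one-to-one matching of predicted points to (merged) gt targets.

    Distance from a prediction to a target is the minimum over the target's
    member centroids, so a telophase pair is hit by a prediction near either
    lobe yet can only be counted once.  ``surplus`` chooses what happens to
    extra predictions within ``max_dist`` of an already-matched target:
    ``"suppress"`` (default) drops them from the count, ``"fp"`` counts them
    as false positives.
    """
    if surplus not in ("suppress", "fp"):
        raise ValueError("surplus must be 'suppress' or 'fp'")
    preds = np.asarray(pred_points, dtype=float).reshape(-1, 2)
    targets, gt = _merge_targets(gt_centroids, groups)
    if len(preds) and len(targets):
        dists = np.full((len(preds), len(targets)), np.inf)
        for ti, members in enumerate(targets):
            d = np.linalg.norm(preds[:, None, :] - gt[members][None, :, :], axis=2)
            dists[:, ti] = d.min(axis=1)
        candidates = [
            (dists[pi, ti], ti, pi)
            for pi in range(len(preds))
            for ti in range(len(targets))
            if dists[pi, ti] <= max_dist
        ]
        candidates.sort()
    else:
        dists = np.zeros((len(preds), len(targets)))
        candidates = []
    used_p, used_t, pairing = set(), set(), []
    for d, ti, pi in candidates:
        if pi in used_p or ti in used_t:
            continue
        pairing.append((ti, pi))
        used_p.add(pi)
        used_t.add(ti)
    suppressed = []
    fp = 0
    for pi in range(len(preds)):
        if pi in used_p:
            continue
        near_matched = any(dists[pi, ti] <= max_dist for ti in used_t)
        if surplus == "suppress" and near_matched:
            suppressed.append(pi)
        else:
            fp += 1
    tp = len(pairing)
    fn = len(targets) - tp
    return MatchResult(tp=tp, fp=fp, fn=fn, pairing=pairing, suppressed=suppressed)


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(match: MatchResult) -> MetricsReport:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F = harmonic mean; guarded."""
    tp, fp, fn = match.tp, match.fp, match.fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if tp == 0:
        return MetricsReport(precision=0.0, recall=0.0, f_score=0.0)
    return MetricsReport(precision=precision, recall=recall, f_score=f_score(precision, recall))


def pr_curve(
    pred_points: Sequence[tuple],
    scores: Sequence[float],
    gt_centroids: Sequence[tuple],
    max_dist: float = DEFAULT_MATCH_DIST,
    groups: Sequence | None = None,
    default_threshold: float = 0.5,
) -> MetricsReport:
    """Threshold sweep over the unique scores with re-matching at each level.

    Points are (recall, precision) ordered by decreasing threshold; the AUC
    is the step-wise rectangle sum over recall.  The headline
    precision/recall/F fields are evaluated at ``default_threshold``
    (predictions with score strictly above it).
    """
    scores = np.asarray(scores, dtype=float)
    preds = np.asarray(pred_points, dtype=float).reshape(-1, 2)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    points = []
    auc = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores.tolist()), reverse=True):
        keep = scores >= thr
        match = match_detections(preds[keep], scores[keep], gt_centroids, max_dist, groups)
        rep = compute_metrics(match)
        points.append((rep.recall, rep.precision))
        auc += max(rep.recall - prev_recall, 0.0) * rep.precision
        prev_recall = max(prev_recall, rep.recall)
    at_default = compute_metrics(
        match_detections(preds[scores > default_threshold], None, gt_centroids, max_dist, groups)
    )
    return MetricsReport(
        precision=at_default.precision,
        recall=at_default.recall,
        f_score=at_default.f_score,
        pr_points=points,
        pr_auc=auc,
    )
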