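"""Presence-background and reference-range evaluation of predictions.

Confusion-table metrics (recall, false positive rate, precision, F1),
ROC and precision-recall curves with their areas, maximum-F1 threshold
search and the no-omission threshold.  A cell counts as predicted present
when its score is >= the threshold.  Ties in ROC ranking are handled by
midranks, so the AUC equals the Mann-Whitney probability
P(pos > neg) + 0.5 P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .grid import RegionMask

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_at_threshold",
    "metrics",
    "roc_auc",
    "pr_auc",
    "max_f1",
    "binary_thresholds",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class EvalReport:
    auc: float
    auc_pr: float
    max_f1: float
    threshold_no_omission: float
    threshold_max_f1: float
    reference: str  # presence_background | expert_range


def _check(scores_pos, scores_neg) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(scores_pos, dtype=float).ravel()
    neg = np.asarray(scores_neg, dtype=float).ravel()
    if pos.size < 1 or neg.size < 1:
        raise ValueError("need at least one positive and one negative score")
    return pos, neg


def confusion_at_threshold(scores_pos, scores_neg, t: float) -> ConfusionCounts:
    """Tally the confusion table with 'present' meaning score >= t."""
    pos, neg = _check(scores_pos, scores_neg)
    tp = int((pos >= t).sum())
    fp = int((neg >= t).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=pos.size - tp, tn=neg.size - fp)


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Recall, false positive rate, precision and F1 from a confusion table.

    Precision (and hence F1) is undefined when nothing is predicted
    present; undefined values are reported as NaN rather than an error.
    """
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) else float("nan")
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * (precision * recall) / (precision + recall)
    return {"recall": recall, "fpr": fpr, "precision": precision, "f1": f1}


def roc_auc(scores_pos, scores_neg) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic (midranks)."""
    pos, neg = _check(scores_pos, scores_neg)
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def _curve_points(pos: np.ndarray, neg: np.ndarray):
    """(recall, precision) at every distinct observed score as threshold,
    thresholds descending (recall non-decreasing)."""
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    recalls, precisions = [], []
    for t in thresholds:
        tp = (pos >= t).sum()
        fp = (neg >= t).sum()
        recalls.append(tp / pos.size)
        precisions.append(tp / (tp + fp) if (tp + fp) else np.nan)
    return np.array(recalls), np.array(precisions)


def pr_auc(scores_pos, scores_neg) -> float:
    """Area under the precision-recall curve, trapezoidal in recall.

    The curve is evaluated at every distinct observed score used as a
    threshold; precision at recall -> 0 is anchored at the precision of
    the highest threshold.
    """
    pos, neg = _check(scores_pos, scores_neg)
    recalls, precisions = _curve_points(pos, neg)
    # anchor the curve at recall 0 with the first defined precision
    first_prec = precisions[~np.isnan(precisions)][0]
    r = np.concatenate([[0.0], recalls])
    p = np.concatenate([[first_prec], np.nan_to_num(precisions, nan=first_prec)])
    return float(np.trapezoid(p, r))


def max_f1(scores_pos, scores_neg) -> tuple[float, float]:
    """Maximum F1 over all distinct observed scores used as thresholds.

    Returns ``(best_f1, threshold)``; the lowest optimal threshold wins
    ties.
    """
    pos, neg = _check(scores_pos, scores_neg)
    thresholds = np.unique(np.concatenate([pos, neg]))  # ascending
    best = (-1.0, float("nan"))
    for t in thresholds:
        f1 = metrics(confusion_at_threshold(pos, neg, t))["f1"]
        if not np.isnan(f1) and f1 > best[0] + 1e-15:
            best = (float(f1), float(t))
    return best


def binary_thresholds(prediction_scores: np.ndarray, presence_idx, background_idx) -> dict[str, float]:
    """Cut-offs for converting a prediction into binary range maps.

    ``no_omission`` is the minimum predicted value over presence cells —
    binarizing there keeps every presence (recall 1).  ``max_f1`` is the
    threshold maximizing F1 against the background.
    """
    scores = np.asarray(prediction_scores, dtype=float)
    pos = scores[presence_idx]
    if pos.size < 1:
        raise ValueError("need at least one presence with a prediction value")
    neg = scores[background_idx]
    _, t_f1 = max_f1(pos, neg)
    return {"no_omission": float(pos.min()), "max_f1": t_f1}


def evaluate(
    prediction: np.ndarray,
    positives_mask: RegionMask,
    native: RegionMask,
    mode: str = "presence_background",
) -> EvalReport:
    """Score a per-cell prediction against positives within the native region.

    ``prediction`` is a vector aligned with ``native.cells()`` (row-major
    member order).  Positives are the member cells of ``positives_mask``
    (presence cells, or an expert reference range already filtered to
    native/extant); negatives are all other native cells.
    """
    if mode not in ("presence_background", "expert_range"):
        raise ValueError(f"unknown mode {mode!r}")
    rows, cols = native.cells()
    is_pos = positives_mask.member[rows, cols]
    if not positives_mask.member[~native.member].sum() == 0 and mode == "expert_range":
        raise ValueError("positives_mask extends outside the native region")
    scores = np.asarray(prediction, dtype=float)
    if scores.shape[0] != rows.shape[0]:
        raise ValueError("prediction not aligned with native cells")
    pos = scores[is_pos]
    neg = scores[~is_pos]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("degenerate class balance: positives or negatives empty")
    f1_best, t_f1 = max_f1(pos, neg)
    return EvalReport(
        auc=roc_auc(pos, neg),
        auc_pr=pr_auc(pos, neg),
        max_f1=f1_best,
        threshold_no_omission=float(pos.min()),
        threshold_max_f1=t_f1,
        reference=mode,
    )
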