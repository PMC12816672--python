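"""Cover-weighted detection scoring: Precision, Recall, F1, IoU.

Confusion counts are weighted by per-pixel sub-pixel cover (chi) so that a
pixel's influence scales with how much algae it actually holds: matched
cover counts toward TP, hallucinated cover toward FP, and missed cover
toward FN.  Setting every chi to 1 recovers plain binary pixel counting.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["MetricsReport", "weighted_confusion", "score", "evaluate_pairs"]


@dataclass(frozen=True)
class MetricsReport:
    """Weighted confusion totals plus the four derived percentage metrics."""

    tp: float
    fp: float
    fn: float
    precision: float
    recall: float
    f1: float
    iou: float
    n_images: int = 1
    weighting: str = "chi(min/excess)"
    per_image: tuple = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_image"] = [dict(p) if isinstance(p, dict) else asdict(p) for p in self.per_image]
        return d


def weighted_confusion(
    pred_mask: np.ndarray,
    truth_mask: np.ndarray,
    chi_pred: np.ndarray | None = None,
    chi_truth: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Chi-weighted (tp, fp, fn) totals for one prediction/truth pair.

    tp = sum over jointly positive pixels of min(chi_pred, chi_truth);
    fp = sum over prediction-only pixels of chi_pred;
    fn = sum over truth-only pixels of chi_truth, plus the shortfall
    max(0, chi_truth - chi_pred) on jointly positive pixels.

    With ``chi_pred``/``chi_truth`` omitted, every positive pixel carries
    weight 1 and the totals reduce to binary pixel counts.
    """
    pred_mask = np.asarray(pred_mask, dtype=bool)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if pred_mask.shape != truth_mask.shape:
        raise ValueError(f"grid mismatch: {pred_mask.shape} vs {truth_mask.shape}")
    wp = np.where(pred_mask, 1.0, 0.0) if chi_pred is None else np.where(pred_mask, chi_pred, 0.0)
    wt = (
        np.where(truth_mask, 1.0, 0.0)
        if chi_truth is None
        else np.where(truth_mask, chi_truth, 0.0)
    )
    both = pred_mask & truth_mask
    tp = float(np.minimum(wp, wt)[both].sum())
    fp = float(wp[pred_mask & ~truth_mask].sum())
    fn = float(wt[truth_mask & ~pred_mask].sum()) + float(
        np.maximum(0.0, wt - wp)[both].sum()
    )
    return tp, fp, fn


def score(tp: float, fp: float, fn: float, n_images: int = 1, per_image=()) -> MetricsReport:
    """Precision/Recall/F1/IoU (percentages) from confusion totals."""
    if tp + fp + fn <= 0:
        raise ValueError("confusion totals are all zero; nothing to score")
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    iou = 100.0 * tp / (tp + fp + fn)
    return MetricsReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        iou=iou,
        n_images=n_images,
        per_image=tuple(per_image),
    )


def evaluate_pairs(pairs) -> MetricsReport:
    """Micro-averaged report over (pred_mask, truth_mask[, chi_pred, chi_truth]) tuples.

    Confusion totals are pooled across images before scoring; per-image
    reports ride along in ``per_image``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no image pairs to evaluate")
    totals = np.zeros(3)
    per_image = []
    for pair in pairs:
        tp, fp, fn = weighted_confusion(*pair)
        totals += (tp, fp, fn)
        per_image.append(score(tp, fp, fn).to_dict() if tp + fp + fn > 0 else
                         {"tp": tp, "fp": fp, "fn": fn})
    return score(*totals, n_images=len(pairs), per_image=per_image)
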