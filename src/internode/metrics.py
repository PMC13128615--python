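"""Segmentation evaluation: pixel precision/recall, AP, and mAP@0.5.

Two faces of the same metrics, matching how segmentation work reports them:

* pixel-level P/R for hard class masks (TP/FP/FN counted per pixel),
* detection-style average precision over confidence-scored predictions,
  where a prediction is "correct" at mask-IoU >= 0.5, averaged across
  classes into mAP@0.5.
"""

from __future__ import annotations

import numpy as np

from .io_formats import LabeledMask


def pixel_pr(pred_mask: LabeledMask, true_mask: LabeledMask, cls: int) -> tuple[float, float]:
    """Pixel precision and recall for one class.

    P = TP/(TP+FP), R = TP/(TP+FN). When the class is absent from both
    masks the scores are defined as 1.0 (nothing to find, nothing found
    wrongly); absent from only one side gives 0.0 for the undefined ratio.
    """
    if pred_mask.data.shape != true_mask.data.shape:
        raise ValueError(
            f"shape mismatch {pred_mask.data.shape} vs {true_mask.data.shape}"
        )
    pred = pred_mask.class_pixels(cls)
    true = true_mask.class_pixels(cls)
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    if tp + fp + fn == 0:
        return 1.0, 1.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (empty/empty -> 0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.sum(a | b)
    return float(np.sum(a & b) / union) if union else 0.0


def average_precision(scored_preds, n_truth: int, method: str = "envelope") -> float:
    """AP from (confidence, is_correct) pairs against ``n_truth`` instances.

    Predictions are sorted by descending confidence; precision is
    accumulated along the recall axis and integrated either with the
    all-point interpolated precision envelope (default) or the classic
    11-point rule. ``n_truth == 0`` with any predictions gives 0; with no
    predictions either, the AP is vacuously 1.
    """
    if method not in {"envelope", "11point"}:
        raise ValueError(f"unknown AP method {method!r}")
    preds = sorted(scored_preds, key=lambda t: -float(t[0]))
    if n_truth == 0:
        return 0.0 if preds else 1.0
    if not preds:
        return 0.0

    correct = np.array([bool(c) for _, c in preds])
    tp = np.cumsum(correct)
    precision = tp / np.arange(1, len(preds) + 1)
    recall = tp / n_truth

    # monotone non-increasing precision envelope
    envelope = np.maximum.accumulate(precision[::-1])[::-1]

    if method == "11point":
        levels = np.linspace(0, 1, 11)
        vals = [envelope[recall >= r].max() if (recall >= r).any() else 0.0 for r in levels]
        return float(np.mean(vals))

    # all-point: sum precision at each recall increment
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * envelope))


def mean_ap(per_class_ap) -> float:
    """Arithmetic mean of per-class AP values (mAP)."""
    aps = np.asarray(list(per_class_ap), dtype=float)
    if aps.size == 0:
        raise ValueError("need at least one class AP")
    return float(aps.mean())


def segmentation_report(pred_masks, true_masks, classes=(0, 1, 2)) -> dict:
    """Per-class pixel P/R pooled over a set of mask pairs, plus means.

    TP/FP/FN are pooled across images before forming the ratios, so large
    images weigh proportionally to their pixel count.
    """
    totals = {c: [0, 0, 0] for c in classes}  # TP, FP, FN
    for pred, true in zip(pred_masks, true_masks):
        if pred.data.shape != true.data.shape:
            raise ValueError("mask pair shape mismatch")
        for c in classes:
            p = pred.class_pixels(c)
            t = true.class_pixels(c)
            totals[c][0] += int(np.sum(p & t))
            totals[c][1] += int(np.sum(p & ~t))
            totals[c][2] += int(np.sum(~p & t))
    report: dict = {"per_class": {}}
    ps, rs = [], []
    for c in classes:
        tp, fp, fn = totals[c]
        if tp + fp + fn == 0:
            prec = rec = 1.0
        else:
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
        report["per_class"][str(c)] = {"precision": prec, "recall": rec}
        ps.append(prec)
        rs.append(rec)
    report["mean_precision"] = float(np.mean(ps))
    report["mean_recall"] = float(np.mean(rs))
    return report
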