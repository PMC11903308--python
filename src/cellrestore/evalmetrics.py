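"""Instance-segmentation evaluation: IoU matching, AP and TP/FP/FN rates.

A predicted label image is scored against ground truth by one-to-one
matching of instances on IoU.  At a threshold t, matched pairs with
IoU >= t are true positives, unmatched predictions are false positives and
unmatched ground-truth instances are false negatives; the average
precision of one image is AP = TP / (TP + FP + FN).  Set-level scores
average the per-image AP (not pooled counts), and TP/FP/FN rates are the
per-image counts normalized by the number of ground-truth instances,
averaged across images.

Matching maximizes the number of above-threshold pairs (assignment on a
cost that rewards an above-threshold match by 1 and breaks ties by total
IoU), so it coincides with exhaustive maximum-cardinality matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linear_sum_assignment

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.91, 0.05), 2))


@dataclass
class MatchResult:
    """TP/FP/FN counts and AP for one image at one IoU threshold."""

    iou_threshold: float
    tp: int
    fp: int
    fn: int
    ap: float


def _label_counts(masks: np.ndarray) -> np.ndarray:
    k = int(masks.max(initial=0))
    return np.bincount(masks.ravel(), minlength=k + 1)


def iou_matrix(pred_masks: np.ndarray, gt_masks: np.ndarray) -> np.ndarray:
    """(n_pred, n_gt) matrix of pairwise instance IoU values.

    Overlaps are accumulated sparsely over co-occurring label pairs, so the
    cost is linear in image size plus the number of overlapping pairs.
    """
    pred_masks = np.asarray(pred_masks)
    gt_masks = np.asarray(gt_masks)
    if pred_masks.shape != gt_masks.shape:
        raise ValueError("pred and gt label images must share shape")
    n_pred = int(pred_masks.max(initial=0))
    n_gt = int(gt_masks.max(initial=0))
    if n_pred == 0 or n_gt == 0:
        return np.zeros((n_pred, n_gt))
    overlap = sparse.coo_matrix(
        (
            np.ones(pred_masks.size, dtype=np.int64),
            (pred_masks.ravel(), gt_masks.ravel()),
        ),
        shape=(n_pred + 1, n_gt + 1),
    ).toarray()[1:, 1:]
    areas_p = _label_counts(pred_masks)[1:]
    areas_g = _label_counts(gt_masks)[1:]
    union = areas_p[:, None] + areas_g[None, :] - overlap
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, overlap / union, 0.0)
    return iou


def match_and_score(
    pred_masks: np.ndarray, gt_masks: np.ndarray, iou_threshold: float = 0.5
) -> MatchResult:
    """One-to-one instance matching at ``iou_threshold``; AP = TP/(TP+FP+FN).

    The empty-vs-empty case scores AP = 1 (nothing to find, nothing
    predicted); empty predictions against nonempty ground truth score 0.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    iou = iou_matrix(pred_masks, gt_masks)
    n_pred, n_gt = iou.shape
    if n_pred == 0 and n_gt == 0:
        return MatchResult(iou_threshold, 0, 0, 0, 1.0)
    tp = 0
    if n_pred and n_gt:
        n_min = min(n_pred, n_gt)
        # reward each above-threshold match by 1; tie-break on total IoU with
        # a term too small to ever trade away a match
        cost = -(iou >= iou_threshold).astype(np.float64) - iou / (2.0 * n_min)
        rows, cols = linear_sum_assignment(cost)
        tp = int(np.sum(iou[rows, cols] >= iou_threshold))
    fp = n_pred - tp
    fn = n_gt - tp
    denom = tp + fp + fn
    ap = tp / denom if denom > 0 else 1.0
    return MatchResult(iou_threshold, tp, fp, fn, ap)


def evaluate_set(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    thresholds=DEFAULT_THRESHOLDS,
) -> dict:
    """Image-averaged AP curve plus normalized TP/FP/FN rates.

    ``pairs`` is a list of (pred_masks, gt_masks).  Returns a dict with
    per-image APs per threshold, the image-averaged ``mean_ap`` curve, and
    ``tp_rate``/``fp_rate``/``fn_rate`` averaged over images with at least
    one ground-truth instance.
    """
    if not pairs:
        raise ValueError("evaluate_set requires at least one (pred, gt) pair")
    thresholds = list(thresholds)
    per_image = np.zeros((len(pairs), len(thresholds)))
    rates = []
    for i, (pred, gt) in enumerate(pairs):
        for j, t in enumerate(thresholds):
            res = match_and_score(pred, gt, t)
            per_image[i, j] = res.ap
            if j == 0:
                n_gt = res.tp + res.fn
                if n_gt > 0:
                    rates.append((res.tp / n_gt, res.fp / n_gt, res.fn / n_gt))
    rates = np.asarray(rates) if rates else np.zeros((0, 3))
    return {
        "thresholds": thresholds,
        "per_image_ap": per_image,
        "mean_ap": per_image.mean(axis=0),
        "tp_rate": float(rates[:, 0].mean()) if len(rates) else float("nan"),
        "fp_rate": float(rates[:, 1].mean()) if len(rates) else float("nan"),
        "fn_rate": float(rates[:, 2].mean()) if len(rates) else float("nan"),
    }
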