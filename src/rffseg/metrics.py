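"""Dice-based training loss and segmentation evaluation metrics.

Evaluation reports, per test image, sensitivity, specificity, Dice,
intersection-over-union, geometric mean sqrt(Sen * Spe) and the pixel-wise
ROC AUC — all as percentages — then aggregates mean and standard deviation
across images. Metrics whose denominator vanishes on an image (e.g.
sensitivity on an empty mask, AUC on a single-class mask) are excluded from
the aggregates and counted, not zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "dice_loss",
    "dice_similarity",
    "confusion",
    "metrics_from_counts",
    "auc",
    "metric_record",
    "evaluate_predictions",
    "evaluate",
]

EPS = 1.0  # Dice-loss regularizer; rescues the empty-vs-empty case

METRIC_NAMES = ("sen", "spe", "dice", "iou", "gm", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int


def dice_similarity(M: np.ndarray, M_hat: np.ndarray) -> float:
    """Soft Dice similarity (2 sum(M*M_hat) + eps) / (sum M + sum M_hat + eps)."""
    M = np.asarray(M, dtype=np.float64)
    M_hat = np.asarray(M_hat, dtype=np.float64)
    if M.shape != M_hat.shape:
        raise ValueError("mask and prediction shapes differ")
    num = 2.0 * float((M * M_hat).sum()) + EPS
    den = float(M.sum()) + float(M_hat.sum()) + EPS
    return num / den


def dice_loss(M: np.ndarray, M_hat: np.ndarray) -> float:
    """1 - soft Dice similarity; 0 at perfect overlap, < 1 always."""
    return 1.0 - dice_similarity(M, M_hat)


def confusion(M: np.ndarray, M_hat_bin: np.ndarray) -> ConfusionCounts:
    """Exact pixel confusion counts between two binary masks."""
    M = np.asarray(M).astype(bool)
    M_hat_bin = np.asarray(M_hat_bin).astype(bool)
    if M.shape != M_hat_bin.shape:
        raise ValueError("mask shapes differ")
    return ConfusionCounts(
        tp=int((M & M_hat_bin).sum()),
        tn=int((~M & ~M_hat_bin).sum()),
        fp=int((~M & M_hat_bin).sum()),
        fn=int((M & ~M_hat_bin).sum()),
    )


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """Sen/Spe/Dice/IOU/GM percentages from confusion counts.

    Undefined ratios (zero denominator) are returned as NaN.
    """
    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    sen = ratio(c.tp, c.tp + c.fn)
    spe = ratio(c.tn, c.tn + c.fp)
    dice = ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp)
    iou = ratio(c.tp, c.tp + c.fn + c.fp)
    gm = float(np.sqrt(sen * spe)) if np.isfinite(sen) and np.isfinite(spe) \
        else float("nan")
    return {"sen": sen, "spe": spe, "dice": dice, "iou": iou, "gm": gm}


def auc(M: np.ndarray, prob: np.ndarray) -> float:
    """Pixel-wise ROC area (trapezoidal over all decision thresholds), x100.

    NaN when the mask contains a single class, since no ranking is defined.
    """
    M = np.asarray(M)
    prob = np.asarray(prob, dtype=np.float64)
    if M.shape != prob.shape:
        raise ValueError("mask and probability shapes differ")
    y = M.ravel().astype(int)
    if y.min() == y.max():
        log.warning("single-class mask: AUC undefined, excluded")
        return float("nan")
    return 100.0 * float(roc_auc_score(y, prob.ravel()))


def metric_record(M: np.ndarray, prob: np.ndarray,
                  threshold: float = 0.5) -> dict:
    """Full per-image record: threshold at 0.5 for counts, raw probs for AUC."""
    rec = metrics_from_counts(confusion(M, np.asarray(prob) >= threshold))
    rec["auc"] = auc(M, prob)
    return rec


def evaluate_predictions(masks, probs, ids=None, threshold: float = 0.5):
    """Per-image records plus mean/std aggregates.

    Returns ``(records_df, summary)`` where ``summary`` maps each metric to
    mean, std and the count of images where it was defined.
    """
    masks, probs = list(masks), list(probs)
    if not masks:
        raise ValueError("empty test set")
    if ids is None:
        ids = list(range(len(masks)))
    rows = []
    for i, (m, p) in enumerate(zip(masks, probs)):
        rows.append({"id": ids[i], **metric_record(m, p, threshold)})
    df = pd.DataFrame(rows)
    summary = {}
    for name in METRIC_NAMES:
        vals = df[name].dropna()
        summary[name] = {
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "std": float(vals.std(ddof=0)) if len(vals) else float("nan"),
            "n_defined": int(len(vals)),
            "n_excluded": int(len(df) - len(vals)),
        }
    return df, summary


def evaluate(model, pairs, threshold: float = 0.5):
    """Run a trained segmenter on image/mask pairs and score it."""
    images = np.stack([p.image for p in pairs])
    probs = model.predict_proba(images)
    masks = [p.mask for p in pairs]
    return evaluate_predictions(masks, list(probs), threshold=threshold)
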