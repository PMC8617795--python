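"""Explanation maps and quantitative interpretability measures.

An explanation map I_tilde = S_tilde * I keeps only the image content the
normalized saliency map S_tilde highlights. Feeding it back through the
network up to the linear logit layer yields a perturbed class-conditional
score y_tilde; comparing y_tilde with the original score y over a test set
gives two faithfulness measures:

* Increase Confidence: the percentage of images whose explanation map
  raises the score (ideal 100%) — the highlighted regions alone carry the
  evidence the model uses;
* Win(r, r'): the percentage of images where model r's explained score
  beats model r''s, a pairwise comparison of explanation quality.

Both use strict inequality; ties count toward neither side, so
Win(a,b) + Win(b,a) = 100 only holds tie-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .camseg import cam_for_image, class_conditional_score, normalize_saliency

log = logging.getLogger(__name__)

__all__ = [
    "ExplanationRecord",
    "explanation_map",
    "explained_score",
    "explanation_records",
    "increase_confidence",
    "win",
    "region_average_heatmap",
]


@dataclass(frozen=True)
class ExplanationRecord:
    image_id: object
    y: float          # class-conditional score of the original image
    y_tilde: float    # score after the explanation-map forward pass
    class_label: int


def explanation_map(I: np.ndarray, S_norm: np.ndarray) -> np.ndarray:
    """Elementwise product of the image with a normalized saliency map."""
    I = np.asarray(I, dtype=np.float64)
    S_norm = np.asarray(S_norm, dtype=np.float64)
    if I.shape != S_norm.shape:
        raise ValueError("image and saliency shapes differ")
    return S_norm * I


def explained_score(model, I_tilde: np.ndarray, M: np.ndarray,
                    lam: int) -> float:
    """Forward an (explanation-map) image to the linear logits, then score.

    The network is evaluated up to its penultimate, linear-activation layer
    G, and the class-conditional mean over mask pixels of class ``lam`` is
    returned.
    """
    _, logits, _ = model.forward_full(np.asarray(I_tilde, dtype=np.float32)[None])
    return class_conditional_score(logits.data[0, ..., 0], M, lam)


def explanation_records(model, pairs, lam: int = 1, layer: str | None = None,
                        ids=None):
    """Full pipeline per image: CAM -> normalize -> explanation map -> rescore."""
    if ids is None:
        ids = list(range(len(pairs)))
    records = []
    for i, pair in zip(ids, pairs):
        s = normalize_saliency(cam_for_image(model, pair.image, pair.mask,
                                             lam, layer))
        itilde = explanation_map(pair.image, s)
        records.append(ExplanationRecord(
            image_id=i,
            y=explained_score(model, pair.image, pair.mask, lam),
            y_tilde=explained_score(model, itilde, pair.mask, lam),
            class_label=lam))
    return records


def increase_confidence(records) -> float:
    """Percentage of records whose explained score strictly exceeds the original."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    return 100.0 * sum(r.y_tilde > r.y for r in records) / len(records)


def win(scores_r, scores_r2) -> float:
    """Percentage of paired images where model r strictly beats model r'."""
    scores_r, scores_r2 = list(scores_r), list(scores_r2)
    if len(scores_r) != len(scores_r2):
        raise ValueError("score lists must pair up image by image")
    if not scores_r:
        raise ValueError("no scores")
    n_win = sum(a > b for a, b in zip(scores_r, scores_r2))
    return 100.0 * n_win / len(scores_r)


def region_average_heatmap(maps, masks, canvas: int = 64):
    """Pixel-wise median of mask-cropped, rescaled saliency maps.

    Each normalized map is cropped to its mask's bounding box, bilinearly
    rescaled to a ``canvas`` x ``canvas`` grid, and the median across
    samples is taken (robust to outlier images). Returns
    ``(median_map, median_mask)``; empty-mask samples are skipped with a
    logged warning.
    """
    maps, masks = list(maps), list(masks)
    if not maps or len(maps) != len(masks):
        raise ValueError("need non-empty, paired map and mask lists")
    crops, mask_crops = [], []
    for i, (m, msk) in enumerate(zip(maps, masks)):
        grid = m.grid if hasattr(m, "grid") else np.asarray(m, dtype=float)
        msk = np.asarray(msk)
        rows, cols = np.nonzero(msk)
        if rows.size == 0:
            log.warning("sample %d has an empty mask: skipped", i)
            continue
        sl = (slice(rows.min(), rows.max() + 1),
              slice(cols.min(), cols.max() + 1))
        crops.append(resize(normalize_saliency(grid)[sl], (canvas, canvas),
                            order=1, mode="edge", anti_aliasing=False))
        mask_crops.append(resize(msk[sl].astype(float), (canvas, canvas),
                                 order=1, mode="edge", anti_aliasing=False))
    if not crops:
        raise ValueError("all masks were empty")
    return (np.median(np.stack(crops), axis=0),
            np.median(np.stack(mask_crops), axis=0))
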