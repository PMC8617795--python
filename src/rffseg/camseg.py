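"""Grad-CAM++ extended to semantic segmentation.

Classification CAM methods need a scalar class score; segmentation produces
a score per pixel. The extension collapses the pre-activation logit grid G
to a class-conditional scalar

    y(lambda) = mean{ G_ij : M_ij = lambda },     lambda in {0, 1},

i.e. the mean logit over the pixels the mask assigns to class lambda, and
then runs Grad-CAM++ against that scalar: per-channel weights

    gamma_d = sum_ij alpha_ij^d * ReLU(dy/dF_ij^d),
    alpha_ij^d = g_ij^2 / (2 g_ij^2 + (sum_ab F_ab^d) g_ij^3),  g = dy/dF^d,

(the usual first-order substitution for the second/third derivative form,
exact when the score is the exponential of a linear function of the
features), and the saliency map is the ReLU of the gamma-weighted channel
sum, bilinearly upsampled to image resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from ._autodiff import Tensor

__all__ = [
    "SaliencyMap",
    "class_conditional_score",
    "gradcampp_alpha",
    "gradcampp_alpha_from_derivatives",
    "gradcampp_weights",
    "gradcampp_weights_from_derivatives",
    "saliency_map",
    "normalize_saliency",
    "cam_for_image",
    "save_heatmap",
]


@dataclass(frozen=True)
class SaliencyMap:
    grid: np.ndarray          # R x C, non-negative
    layer_name: str
    class_label: int


def class_conditional_score(G: np.ndarray, M: np.ndarray, lam: int) -> float:
    """Mean logit over the pixels of class ``lam``; error if none exist."""
    G = np.asarray(G, dtype=np.float64)
    M = np.asarray(M)
    if G.shape != M.shape:
        raise ValueError("logit grid and mask shapes differ")
    sel = M == lam
    if not sel.any():
        raise ValueError(f"no pixels of class {lam}: score undefined")
    return float(G[sel].mean())


def _alpha(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with the 0/0 convention -> 0 (no feature, no credit)."""
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den != 0)
    return out


def gradcampp_alpha(F_l: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Closed-form alpha grid g^2 / (2 g^2 + (sum F) g^3), g the score gradient.

    This is the first-order substitution for the second/third-derivative
    form, exact (up to an overall positive scale on the final weights) when
    the class score is exponentiated before differentiation.
    """
    F_l = np.asarray(F_l, dtype=np.float64)
    g = np.asarray(grad, dtype=np.float64)
    if F_l.shape != g.shape:
        raise ValueError("feature and gradient shapes differ")
    g2, g3 = g ** 2, g ** 3
    denom = 2.0 * g2 + F_l.sum(axis=(0, 1), keepdims=True) * g3
    return _alpha(g2, denom)


def gradcampp_weights(F_l: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Per-channel Grad-CAM++ weights gamma_d = sum_ij alpha_ij ReLU(g_ij).

    ``F_l`` and ``grad`` are R_l x C_l x D grids; returns a length-D vector.
    """
    g = np.asarray(grad, dtype=np.float64)
    alpha = gradcampp_alpha(F_l, g)
    return (alpha * np.maximum(g, 0.0)).sum(axis=(0, 1))


def gradcampp_alpha_from_derivatives(F_l, d2, d3) -> np.ndarray:
    """Alpha grid from explicit 2nd/3rd derivative grids of the class score.

    Evaluates the derivative form alpha = d2 / (2 d2 + (sum F) d3) directly,
    with no substitution; used to cross-check :func:`gradcampp_alpha` on
    models whose higher derivatives are known in closed form.
    """
    F_l, d2, d3 = (np.asarray(a, dtype=np.float64) for a in (F_l, d2, d3))
    denom = 2.0 * d2 + F_l.sum(axis=(0, 1), keepdims=True) * d3
    return _alpha(d2, denom)


def gradcampp_weights_from_derivatives(F_l, d1, d2, d3) -> np.ndarray:
    """Weights from explicit 1st/2nd/3rd derivative grids of the class score.

    For an exponentiated score y = exp(S) with S linear in the features,
    this equals exp(S) times :func:`gradcampp_weights` evaluated on the
    raw-score gradients — the same saliency map after normalization.
    """
    d1 = np.asarray(d1, dtype=np.float64)
    alpha = gradcampp_alpha_from_derivatives(F_l, d2, d3)
    return (alpha * np.maximum(d1, 0.0)).sum(axis=(0, 1))


def saliency_map(F_l: np.ndarray, gamma: np.ndarray, out_shape,
                 layer_name: str = "", class_label: int = 1) -> SaliencyMap:
    """ReLU of the gamma-weighted channel sum, upsampled to ``out_shape``."""
    F_l = np.asarray(F_l, dtype=np.float64)
    gamma = np.asarray(gamma, dtype=np.float64)
    if F_l.ndim != 3 or gamma.shape != (F_l.shape[-1],):
        raise ValueError("gamma length must equal the channel count")
    s = np.maximum(np.tensordot(F_l, gamma, axes=1), 0.0)
    if tuple(s.shape) != tuple(out_shape):
        s = resize(s, out_shape, order=1, mode="edge", anti_aliasing=False)
        s = np.maximum(s, 0.0)
    return SaliencyMap(grid=s, layer_name=layer_name, class_label=class_label)


def normalize_saliency(S: SaliencyMap | np.ndarray) -> np.ndarray:
    """Divide by the maximum; the all-zero map stays all-zero by convention."""
    grid = S.grid if isinstance(S, SaliencyMap) else np.asarray(S, dtype=float)
    m = grid.max()
    return grid / m if m > 0 else np.zeros_like(grid)


def cam_for_image(model, image: np.ndarray, mask: np.ndarray, lam: int,
                  layer: str | None = None) -> SaliencyMap:
    """End-to-end saliency for one image: score -> gradients -> weights -> map.

    ``layer`` defaults to the convolutional layer just before the RFF
    insertion point (the bottleneck output when the model has no RFF layer).
    """
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    layer = layer or model.cam_layer_name
    _, logits, feats = model.forward_full(image[None])
    if layer not in feats:
        raise KeyError(f"no layer named {layer!r}")
    sel = (mask == lam)
    if not sel.any():
        raise ValueError(f"no pixels of class {lam}: score undefined")
    # y(lambda) as a graph node: masked mean of the logit grid
    wgt = (sel.astype(logits.data.dtype) / sel.sum())[None, ..., None]
    y = (logits * Tensor(wgt)).sum()
    y.backward()
    tap = feats[layer]
    gamma = gradcampp_weights(tap.data[0], tap.grad[0])
    return saliency_map(tap.data[0], gamma, image.shape,
                        layer_name=layer, class_label=lam)


def save_heatmap(path_base: str, S_norm: np.ndarray, image: np.ndarray,
                 alpha: float = 0.5):
    """Write ``<base>.tiff`` (raw 32-bit grid) and ``<base>.png`` (Jet overlay)."""
    import imageio.v3 as iio
    from matplotlib import cm

    iio.imwrite(path_base + ".tiff", S_norm.astype(np.float32))
    heat = cm.jet(np.clip(S_norm, 0, 1))[..., :3]
    gray = np.clip(np.asarray(image, dtype=float), 0, 1)[..., None]
    overlay = (1 - alpha) * gray + alpha * heat
    iio.imwrite(path_base + ".png",
                np.round(np.clip(overlay, 0, 1) * 255).astype(np.uint8))
    return path_base + ".tiff", path_base + ".png"
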