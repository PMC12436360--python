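"""Gradient-weighted class activation maps over the original-image branch.

The fracture logit is differentiated with respect to the patch-token
activations entering the final layer norm of the original-image encoder.
Channel weights are the token-mean gradients; the map is the rectified
weighted sum per token, reshaped to the patch grid, min-max normalized,
and bilinearly upsampled to image resolution.  A single bounding box is
derived from the largest connected super-threshold component — and only
when the model actually predicts a fracture: a negative call yields no
box at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .matching import resize_bilinear
from .model import FusionClassifier

__all__ = ["SaliencyMap", "saliency_map", "heatmap_to_box", "localize_samples"]


@dataclass
class SaliencyMap:
    grid: np.ndarray          # patch-grid resolution, non-negative
    upsampled: np.ndarray     # image resolution
    sample_id: str
    score: float
    all_zero: bool = False    # flagged when gradients vanish everywhere


def saliency_map(
    model: FusionClassifier,
    original: np.ndarray,
    crop: np.ndarray | None = None,
    sample_id: str = "",
) -> SaliencyMap:
    """Activation map for one (original, crop) input pair."""
    cfg = model.config
    original = np.asarray(original, dtype=np.float64)
    if original.shape != (cfg.image_size, cfg.image_size):
        original = resize_bilinear(original, cfg.image_size, cfg.image_size)
    if model.mode == "multi":
        if crop is None:
            raise ValueError("multi-mode model requires a crop input")
        crop = np.asarray(crop, dtype=np.float64)
        if crop.shape != (cfg.image_size, cfg.image_size):
            crop = resize_bilinear(crop, cfg.image_size, cfg.image_size)
        crop = crop[None]
    logits = model.forward_logits(original[None], crop, training=False, capture_tokens=True)
    tokens = model._captured_tokens
    if tokens is None:
        raise ValueError("model did not store patch-token activations")
    logits.backward(np.ones(1))
    if tokens.grad is None:
        raise ValueError("no gradient reached the stored activations")
    acts = tokens.data[0, 1:]      # patch tokens (N, D); row 0 is CLS
    grads = tokens.grad[0, 1:]
    weights = grads.mean(axis=0)   # channel weights: token-mean gradient
    cam = np.maximum(acts @ weights, 0.0)
    g = cfg.image_size // cfg.patch_size
    grid = cam.reshape(g, g)
    all_zero = not np.any(grid > 0)
    if not all_zero:
        grid = grid / grid.max()
    upsampled = resize_bilinear(grid, cfg.image_size, cfg.image_size)
    score = float(1.0 / (1.0 + np.exp(-logits.data[0])))
    return SaliencyMap(grid=grid, upsampled=upsampled, sample_id=sample_id,
                       score=score, all_zero=all_zero)


def heatmap_to_box(
    smap: SaliencyMap,
    activation_threshold: float = 0.5,
    operating_point: float = 0.5,
) -> tuple[int, int, int, int] | None:
    """Bounding box of the dominant activated region, or None.

    None when the model score is below the operating point (a negative
    prediction offers no box) or when no patch cell reaches the
    activation threshold.  Otherwise the tight box, in image-pixel
    coordinates (half-open), of the largest 4-connected component of
    super-threshold patch cells.
    """
    if not (0.0 <= activation_threshold <= 1.0):
        raise ValueError("activation_threshold must lie in [0, 1]")
    if smap.score < operating_point or smap.all_zero:
        return None
    hot = smap.grid >= activation_threshold
    if not hot.any():
        return None
    labeled, n = ndimage.label(hot, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    rows, cols = np.nonzero(labeled == largest)
    g = smap.grid.shape[0]
    ps = smap.upsampled.shape[0] // g
    return (
        int(rows.min()) * ps,
        int(cols.min()) * ps,
        (int(rows.max()) + 1) * ps,
        (int(cols.max()) + 1) * ps,
    )


def localize_samples(
    model: FusionClassifier,
    originals: np.ndarray,
    crops: np.ndarray | None,
    sample_ids: list[str],
    operating_point: float,
    activation_threshold: float = 0.5,
) -> list[dict]:
    """Score + (optional) box per sample; the reader-assistance overlay data."""
    out = []
    for i, sid in enumerate(sample_ids):
        smap = saliency_map(
            model, originals[i], None if crops is None else crops[i], sample_id=sid
        )
        box = heatmap_to_box(smap, activation_threshold, operating_point)
        out.append({"sample_id": sid, "score": smap.score, "box": box})
    return out
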