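"""Overlay rendering: saliency heatmaps and annotator-vote maps.

Saliency is blended over the grayscale montage with a warm colormap
(warmer = stronger attention).  Stacks of annotator masks are rendered as
per-pixel vote counts (0..n annotators), warmer = stronger agreement.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from matplotlib import colormaps

from .errors import AlignmentError


def _gray_rgb(image: np.ndarray) -> np.ndarray:
    g = image.astype(np.float64)
    if g.max() > 1.0:
        g = g / 255.0
    return np.repeat(g[:, :, None], 3, axis=2)


def render_overlay(montage_image: np.ndarray, saliency: np.ndarray | None = None,
                   masks: Sequence[np.ndarray] | None = None,
                   cmap: str = "jet", alpha: float = 0.5) -> np.ndarray:
    """RGB uint8 overlay of a saliency map or an annotator-mask stack.

    With ``saliency`` given, blending weight is ``alpha * value`` so
    zero-saliency pixels show the plain grayscale montage.  With ``masks``,
    per-pixel vote counts are colored; zero-vote pixels stay grayscale.
    """
    if (saliency is None) == (masks is None):
        raise AlignmentError("provide exactly one of saliency or masks")
    base = _gray_rgb(montage_image)
    cm = colormaps[cmap]
    if saliency is not None:
        if saliency.shape != montage_image.shape:
            raise AlignmentError("saliency not aligned with montage")
        heat = cm(np.clip(saliency, 0.0, 1.0))[:, :, :3]
        w = alpha * np.clip(saliency, 0.0, 1.0)[:, :, None]
        out = (1.0 - w) * base + w * heat
    else:
        for m in masks:
            if m.shape != montage_image.shape:
                raise AlignmentError("mask not aligned with montage")
        votes = vote_image(masks)
        frac = votes / max(len(masks), 1)
        heat = cm(frac)[:, :, :3]
        w = alpha * (votes > 0)[:, :, None]
        out = (1.0 - w) * base + w * heat
    return np.clip(np.rint(out * 255), 0, 255).astype(np.uint8)


def vote_image(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel sum of binary masks (annotator agreement counts)."""
    if not len(masks):
        raise AlignmentError("need at least one mask")
    return np.sum([np.asarray(m, dtype=bool).astype(np.int64) for m in masks],
                  axis=0)
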