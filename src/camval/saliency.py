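"""Score-CAM saliency maps and their binarization into S_o and S_h masks.

Score-CAM is gradient-free: each channel of a chosen convolutional layer's
activation is upsampled to input size, min-max normalized to [0, 1]
(constant channels become zeros), and used to mask the input by elementwise
product.  The masked inputs are forward-passed and the increase of the
target-class score over an all-zero baseline input is collected per
channel; a softmax over these increases gives channel weights
``alpha_k``.  The saliency map is ``ReLU(sum_k alpha_k * upsampled A_k)``,
min-max normalized to [0, 1].

Two binary masks are derived from a saliency map:

* ``S_o`` (original): the support of the map above a configurable
  activation floor (default 0 — any nonzero attention counts);
* ``S_h`` (highly activated): pixels above the Otsu threshold computed on a
  256-bin histogram of the map, i.e. the threshold maximizing between-class
  variance.  ``S_h`` is always a subset of ``S_o`` at the default floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .errors import AlignmentError, ConfigurationError
from . import nn


@dataclass
class SaliencyMap:
    values: np.ndarray  # 2D float in [0, 1]
    model_id: str
    target_class: int
    layer_name: str

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise AlignmentError("saliency values must be 2D")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ConfigurationError("saliency values must lie in [0, 1]")


@dataclass
class BinarySaliency:
    mask: np.ndarray  # 2D bool
    variant: str  # "S_o" or "S_h"
    threshold_used: float
    degenerate: bool = False


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def channel_weights(model: nn.Sequential, image: np.ndarray,
                    target_class: int, layer_name: str,
                    interpolation: str = "bilinear",
                    batch_size: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel softmax weights and upsampled raw activations.

    Returns ``(alpha, ups)`` with ``alpha`` summing to 1 and ``ups`` of
    shape (K, H, W).
    """
    if image.ndim != 2:
        raise AlignmentError("montage image must be 2D")
    if image.min() < -1e-12 or image.max() > 1 + 1e-12:
        raise ConfigurationError("score_cam expects a [0, 1]-normalized montage")
    order = {"bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ConfigurationError(f"unknown interpolation {interpolation!r}")

    x = image[None, None, :, :].astype(np.float64)
    _, captured = model.forward(x, capture=[layer_name])
    acts = captured[layer_name][0]  # (K, h, w)
    k = acts.shape[0]
    ups = np.stack([
        resize(acts[c], image.shape, order=order, mode="edge",
               anti_aliasing=False, preserve_range=True)
        for c in range(k)
    ])
    norms = np.stack([_minmax(u) for u in ups])
    masked = (norms * image)[:, None, :, :]
    scores = model.predict_proba(masked, batch_size=batch_size)[:, target_class]
    baseline = model.predict_proba(np.zeros_like(x))[0, target_class]
    alpha = nn.softmax((scores - baseline)[None, :])[0]
    return alpha, ups


def score_cam(model: nn.Sequential, image: np.ndarray, target_class: int,
              layer_name: str, model_id: str = "model",
              interpolation: str = "bilinear", batch_size: int = 32) -> SaliencyMap:
    """Score-CAM saliency for one [0, 1]-normalized montage image."""
    alpha, ups = channel_weights(model, image, target_class, layer_name,
                                 interpolation=interpolation, batch_size=batch_size)
    sal = np.maximum((alpha[:, None, None] * ups).sum(axis=0), 0.0)
    return SaliencyMap(values=_minmax(sal), model_id=model_id,
                       target_class=int(target_class), layer_name=layer_name)


def binarize_original(smap: SaliencyMap, activation_floor: float = 0.0) -> BinarySaliency:
    """S_o: the attention footprint — pixels above the activation floor."""
    return BinarySaliency(mask=smap.values > activation_floor, variant="S_o",
                          threshold_used=float(activation_floor))


def otsu_threshold(values: np.ndarray, bins: int = 256) -> tuple[float, np.ndarray]:
    """Between-class-variance-maximizing threshold on a [0, 1] histogram.

    Returns ``(threshold, sigma_b)`` where ``sigma_b[t]`` is the
    between-class variance of the split after bin ``t`` (candidate
    threshold = upper edge of bin ``t``).
    """
    hist, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    total = hist.sum()
    p = hist / total
    centers = (edges[:-1] + edges[1:]) / 2.0
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=0.0, posinf=0.0)
    t_idx = int(np.argmax(sigma_b))
    return float(edges[t_idx + 1]), sigma_b


def binarize_otsu(smap: SaliencyMap, bins: int = 256) -> BinarySaliency:
    """S_h: highly activated pixels above the Otsu threshold.

    A constant map has no between-class split; it yields an empty mask
    flagged ``degenerate`` with a warning.
    """
    v = smap.values
    if v.min() == v.max():
        warnings.warn("constant saliency map: Otsu threshold undefined, "
                      "returning empty S_h", stacklevel=2)
        return BinarySaliency(mask=np.zeros(v.shape, dtype=bool), variant="S_h",
                              threshold_used=float("nan"), degenerate=True)
    thr, _ = otsu_threshold(v, bins=bins)
    return BinarySaliency(mask=v > thr, variant="S_h", threshold_used=thr)
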