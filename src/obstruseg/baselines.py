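"""Comparison segmenters: Otsu / fixed-threshold and gradient +
hysteresis edge detection."""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny

from .images import GrayImage, LabelMask
from .util import ValidationError

__all__ = ["otsu_threshold", "threshold_segment", "edge_segment"]

logger = logging.getLogger(__name__)

N_OTSU_BINS = 256


def otsu_threshold(image: GrayImage) -> float | None:
    """Between-class-variance-maximising threshold over a 256-bin histogram.

    Returns the upper edge of the last background bin, or None for a
    constant image (no valid split).
    """
    hist, edges = np.histogram(image.pixels, bins=N_OTSU_BINS, range=(0.0, 1.0))
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(hist)[:-1]  # candidate split after bin k, k = 0..254
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    if not np.any(valid):
        return None
    csum = np.cumsum(hist * centers)[:-1]
    mu0 = np.where(valid, csum / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (csum[-1] + hist[-1] * centers[-1] - csum) / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(between))
    return float(edges[k + 1])


def threshold_segment(
    image: GrayImage, method: str = "otsu", fixed_t: float | None = None
) -> LabelMask:
    """Binary mask by intensity thresholding (pixel >= t -> label 1)."""
    if method == "otsu":
        t = otsu_threshold(image)
        if t is None:
            logger.warning("constant image: Otsu threshold undefined, returning all-zero mask")
            return LabelMask(np.zeros(image.shape, dtype=np.int64))
    elif method == "fixed":
        if fixed_t is None or not (0.0 < fixed_t < 1.0):
            raise ValidationError("method='fixed' requires fixed_t in (0, 1)")
        t = fixed_t
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    return LabelMask((image.pixels >= t).astype(np.int64))


def edge_segment(
    image: GrayImage,
    low: float = 0.05,
    high: float = 0.15,
    fill: bool = True,
    sigma: float = 1.0,
) -> LabelMask:
    """Edge mask from Sobel gradient magnitude with non-maximum suppression
    and hysteresis linking (Canny); with ``fill`` the interiors of closed
    contours are filled too."""
    if not (0.0 <= low < high <= 1.0):
        raise ValidationError(f"need 0 <= low < high <= 1, got low={low} high={high}")
    edges = canny(image.pixels, sigma=sigma, low_threshold=low, high_threshold=high)
    if fill:
        edges = ndi.binary_fill_holes(edges)
    return LabelMask(edges.astype(np.int64))
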