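"""Per-block texture/intensity features feeding the block classifier.

Each block maps to a fixed 6-vector: mean, variance, 32-bin histogram
entropy (bits), gradient energy, and co-occurrence contrast/homogeneity on
an 8-level quantization at offset (0, 1), symmetric and normalized.
Histogram and co-occurrence statistics are computed on the block rescaled
to its own [min, max] range, so every feature except the mean is invariant
to adding a constant to all intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix, graycoprops

from .util import ValidationError

__all__ = [
    "FEATURE_NAMES",
    "FeatureScaler",
    "block_features",
    "feature_matrix",
    "fit_scaler",
    "apply_scaler",
]

FEATURE_NAMES = ("mean", "variance", "entropy", "gradient_energy", "contrast", "homogeneity")

N_ENTROPY_BINS = 32
N_GLCM_LEVELS = 8


def _rescaled(block: np.ndarray) -> np.ndarray:
    lo, hi = block.min(), block.max()
    if hi == lo:
        return np.zeros_like(block)
    return (block - lo) / (hi - lo)


def block_features(block: np.ndarray) -> np.ndarray:
    """Compute the 6-feature vector of one intensity patch."""
    block = np.asarray(block, dtype=np.float64)
    if block.size == 0:
        raise ValidationError("empty block")
    if block.ndim != 2:
        raise ValidationError(f"block must be 2-D, got shape {block.shape}")

    mean = float(block.mean())
    variance = float(block.var())

    rel = _rescaled(block)

    hist, _ = np.histogram(rel, bins=N_ENTROPY_BINS, range=(0.0, 1.0))
    p = hist[hist > 0] / block.size
    entropy = float(-(p * np.log2(p)).sum())

    dr = np.diff(block, axis=0)
    dc = np.diff(block, axis=1)
    gradient_energy = float((np.sum(dr**2) + np.sum(dc**2)) / block.size)

    levels = np.minimum((rel * N_GLCM_LEVELS).astype(np.uint8), N_GLCM_LEVELS - 1)
    if block.shape[1] < 2:
        contrast, homogeneity = 0.0, 1.0
    else:
        glcm = graycomatrix(
            levels, distances=[1], angles=[0.0], levels=N_GLCM_LEVELS,
            symmetric=True, normed=True,
        )
        contrast = float(graycoprops(glcm, "contrast")[0, 0])
        homogeneity = float(graycoprops(glcm, "homogeneity")[0, 0])

    return np.array([mean, variance, entropy, gradient_energy, contrast, homogeneity])


def feature_matrix(blocks: np.ndarray) -> np.ndarray:
    """Stack block_features over a (n, b, b) array of patches."""
    return np.stack([block_features(b) for b in blocks])


@dataclass(frozen=True)
class FeatureScaler:
    """Per-dimension z-score parameters; zero-spread dimensions get scale 1."""

    location: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        if np.any(self.scale <= 0):
            raise ValidationError("scaler scale must be positive")


def fit_scaler(samples: np.ndarray) -> FeatureScaler:
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValidationError("need >= 2 feature vectors to fit a scaler")
    loc = samples.mean(axis=0)
    scale = samples.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return FeatureScaler(location=loc, scale=scale)


def apply_scaler(scaler: FeatureScaler, v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return (v - scaler.location) / scaler.scale
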