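"""Grayscale image / label-mask containers, file I/O, and the overlapping-block
decomposition with its probability-averaging reassembly.

Images are carried as float64 rasters in [0, 1]; masks as small non-negative
integer rasters.  Blocks are cut on a row-major stride grid with a final
edge-flush origin per axis so that every pixel is covered by at least one
block (no padding is ever introduced).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

from .util import ValidationError

__all__ = [
    "GrayImage",
    "LabelMask",
    "BlockGrid",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "block_origins",
    "extract_blocks",
    "accumulate_scores",
    "reassemble_mask",
]


@dataclass(frozen=True)
class GrayImage:
    """2-D intensity raster with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(f"image must be 2-D and non-empty, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LabelMask:
    """2-D raster of small non-negative integer labels."""

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise ValidationError("mask labels must be integers")
            lab = lab.astype(np.int64)
        if lab.min() < 0:
            raise ValidationError("mask labels must be non-negative")
        object.__setattr__(self, "labels", lab.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class BlockGrid:
    """Overlapping square patches cut from an image at a fixed stride.

    ``origins`` are row-major (row, col) top-left corners; ``blocks[i]`` is the
    ``block_size`` x ``block_size`` patch at ``origins[i]``.
    """

    block_size: int
    overlap_step: int
    origins: np.ndarray  # (n_blocks, 2) int
    blocks: np.ndarray  # (n_blocks, b, b) float
    source_shape: tuple[int, int]

    @property
    def n_blocks(self) -> int:
        return len(self.origins)


def _normalize(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        # constant image: documented convention, maps to all zeros
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def load_image(path, slice_index: int | None = None) -> GrayImage:
    """Load a PNG/TIFF grayscale or single-slice NIfTI image, min-max
    normalized to [0, 1].

    ``slice_index`` selects a slice from a 3-D NIfTI volume; without it a
    volume with more than one slice is rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ValidationError(f"no such file: {path}")
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(path).dataobj)
        data = np.squeeze(data)
        if data.ndim == 3:
            if slice_index is None:
                if data.shape[2] != 1:
                    raise ValidationError(
                        f"NIfTI volume has {data.shape[2]} slices; pass --slice to pick one"
                    )
                data = data[:, :, 0]
            else:
                data = data[:, :, slice_index]
        if data.ndim != 2:
            raise ValidationError(f"cannot reduce NIfTI of shape {data.shape} to 2-D")
        return GrayImage(_normalize(data))
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValidationError(
            f"multi-channel input not supported (shape {arr.shape}); convert to grayscale first"
        )
    return GrayImage(_normalize(arr))


def save_image(image: GrayImage, path) -> None:
    """Write a GrayImage as 16-bit grayscale PNG or TIFF."""
    path = os.fspath(path)
    arr = np.round(image.pixels * 65535.0).astype(np.uint16)
    iio.imwrite(path, arr)


def save_mask(mask: LabelMask, path) -> None:
    """Write a LabelMask as an 8-bit PNG label image."""
    path = os.fspath(path)
    lab = mask.labels
    if lab.max() > 255:
        raise ValidationError("mask labels exceed 8-bit range")
    iio.imwrite(path, lab.astype(np.uint8))


def save_nifti(image: GrayImage, path) -> None:
    """Write a GrayImage as a single-slice NIfTI volume."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(image.pixels[:, :, None], affine=np.eye(4)), os.fspath(path))


def load_mask(path) -> LabelMask:
    return LabelMask(np.asarray(iio.imread(os.fspath(path)), dtype=np.int64))


def block_origins(length: int, block_size: int, step: int) -> np.ndarray:
    """1-D origins 0, s, 2s, ... plus an edge-flush origin when the last
    stride undershoots, so intervals [o, o+b) cover [0, length)."""
    if step < 1:
        raise ValidationError(f"overlap step must be >= 1, got {step}")
    if block_size > length:
        raise ValidationError(f"block size {block_size} exceeds axis length {length}")
    origins = list(range(0, length - block_size + 1, step))
    if origins[-1] != length - block_size:
        origins.append(length - block_size)
    return np.asarray(origins, dtype=np.int64)


def extract_blocks(image: GrayImage, block_size: int, overlap_step: int) -> BlockGrid:
    """Cut an image into overlapping b x b patches on a row-major stride grid."""
    h, w = image.shape
    if not (1 <= overlap_step <= block_size):
        raise ValidationError(
            f"need 1 <= overlap_step <= block_size, got step={overlap_step} block={block_size}"
        )
    if block_size > min(h, w):
        raise ValidationError(f"block size {block_size} exceeds image {h}x{w}")
    rows = block_origins(h, block_size, overlap_step)
    cols = block_origins(w, block_size, overlap_step)
    origins = np.array([(r, c) for r in rows for c in cols], dtype=np.int64)
    blocks = np.stack(
        [image.pixels[r : r + block_size, c : c + block_size] for r, c in origins]
    )
    return BlockGrid(
        block_size=block_size,
        overlap_step=overlap_step,
        origins=origins,
        blocks=blocks,
        source_shape=(h, w),
    )


def accumulate_scores(grid: BlockGrid, block_scores: np.ndarray) -> np.ndarray:
    """Per-pixel mean of the class-score vectors of all covering blocks.

    Returns an (H, W, K) array; this pre-argmax map is what the graph-cut
    refinement consumes.
    """
    scores = np.asarray(block_scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != grid.n_blocks:
        raise ValidationError(
            f"need one score vector per block ({grid.n_blocks}), got shape {scores.shape}"
        )
    h, w = grid.source_shape
    k = scores.shape[1]
    b = grid.block_size
    acc = np.zeros((h, w, k))
    cover = np.zeros((h, w))
    for (r, c), s in zip(grid.origins, scores):
        acc[r : r + b, c : c + b, :] += s
        cover[r : r + b, c : c + b] += 1.0
    if np.any(cover == 0):
        raise ValidationError("block grid does not cover the image")
    return acc / cover[:, :, None]


def reassemble_mask(grid: BlockGrid, block_scores: np.ndarray, vote: str = "mean") -> LabelMask:
    """Fuse per-block class scores into a per-pixel label map.

    ``vote='mean'`` averages covering blocks' score vectors then takes the
    argmax (ties to the lower class index); ``vote='majority'`` takes a
    majority over covering blocks' argmax labels instead.
    """
    if vote == "mean":
        mean = accumulate_scores(grid, block_scores)
        return LabelMask(np.argmax(mean, axis=2).astype(np.int64))
    if vote == "majority":
        scores = np.asarray(block_scores, dtype=np.float64)
        if scores.ndim != 2 or scores.shape[0] != grid.n_blocks:
            raise ValidationError("need one score vector per block")
        onehot = np.zeros_like(scores)
        onehot[np.arange(len(scores)), np.argmax(scores, axis=1)] = 1.0
        counts = accumulate_scores(grid, onehot)
        return LabelMask(np.argmax(counts, axis=2).astype(np.int64))
    raise ValidationError(f"unknown vote mode {vote!r}")
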