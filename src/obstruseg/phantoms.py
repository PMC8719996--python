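"""Synthetic "ileus phantom" generator.

Produces 2-D grayscale images that mimic the gross phenomenology of
obstructed-bowel MRI slices — dilated elliptical bowel loops containing a
horizontal air-fluid interface (dark gas above, bright fluid below), an
optional soft-tissue lesion with a darker wall ring — together with paired
ground-truth label masks (0 background, 1 lumen, 2 lesion).  Four category
archetypes (parameter templates) exist so that case-level recognition
metrics can be exercised.

Everything is a pure function of (spec, seed): noise is additive zero-mean
Gaussian, applied after the truth mask is drawn, then clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .images import GrayImage, LabelMask
from .util import ValidationError, as_rng, spawn_seeds

__all__ = [
    "LoopSpec",
    "LesionSpec",
    "PhantomSpec",
    "LabeledImagePair",
    "CLASS_NAMES",
    "N_CLASSES",
    "class_template",
    "make_phantom",
    "make_phantom_set",
]

#: The four morphology archetypes (stand-ins for clinical obstruction causes).
CLASS_NAMES = ("mass_round", "mass_walled", "band_twin_loop", "twist_large_loop")
N_CLASSES = len(CLASS_NAMES)

BACKGROUND = 0
LUMEN = 1
LESION = 2


@dataclass(frozen=True)
class LoopSpec:
    """A dilated bowel loop: an ellipse filled with air above / fluid below
    a horizontal interface."""

    center: tuple[float, float]  # (row, col), pixels
    semi_axes: tuple[float, float]  # (row semi-axis, col semi-axis), pixels
    angle: float = 0.0  # radians, counter-clockwise
    lumen_level: float = 0.9  # fluid intensity


@dataclass(frozen=True)
class LesionSpec:
    """A soft-tissue mass: filled ellipse at ``level`` with a darker wall
    ring of ``wall_thickness`` pixels."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float = 0.0
    level: float = 0.6
    wall_thickness: float = 0.0
    wall_level: float | None = None  # default: level - 0.2, floored at 0.05


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 96
    width: int = 96
    background_level: float = 0.25
    loops: tuple[LoopSpec, ...] = ()
    airfluid_fraction: float = 0.35  # top fraction of a loop rendered as air
    air_level: float = 0.05
    lesion: LesionSpec | None = None
    noise_sd: float = 0.0
    class_label: int = 0

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValidationError(f"non-positive image size {self.height}x{self.width}")
        levels = [self.background_level, self.air_level]
        levels += [lp.lumen_level for lp in self.loops]
        if self.lesion is not None:
            levels.append(self.lesion.level)
            if self.lesion.wall_level is not None:
                levels.append(self.lesion.wall_level)
        for lv in levels:
            if not (0.0 <= lv <= 1.0):
                raise ValidationError(f"intensity level {lv} outside [0, 1]")
        if not (0.0 <= self.airfluid_fraction <= 1.0):
            raise ValidationError("airfluid_fraction must lie in [0, 1]")
        if self.noise_sd < 0.0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.class_label < N_CLASSES):
            raise ValidationError(f"class_label must be in [0, {N_CLASSES})")


@dataclass(frozen=True)
class LabeledImagePair:
    image: GrayImage
    truth: LabelMask
    spec: PhantomSpec
    seed: int

    def __post_init__(self):
        if self.image.shape != self.truth.shape:
            raise ValidationError("image and truth shapes differ")


def ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float = 0.0,
) -> np.ndarray:
    """Boolean raster of a (possibly rotated) filled ellipse, clipped to
    the image bounds.  Pixel (i, j) is inside iff its center point is."""
    h, w = shape
    a, b = semi_axes
    if a <= 0 or b <= 0:
        return np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _vertical_extent(loop: LoopSpec) -> float:
    a, b = loop.semi_axes
    ca, sa = math.cos(loop.angle), math.sin(loop.angle)
    return math.sqrt((a * ca) ** 2 + (b * sa) ** 2)


def make_phantom(spec: PhantomSpec, seed: int) -> LabeledImagePair:
    """Render a phantom deterministically from (spec, seed)."""
    shape = (spec.height, spec.width)
    img = np.full(shape, spec.background_level, dtype=np.float64)
    truth = np.zeros(shape, dtype=np.int64)
    rows = np.arange(spec.height)[:, None]

    for loop in spec.loops:
        inside = ellipse_mask(shape, loop.center, loop.semi_axes, loop.angle)
        ext = _vertical_extent(loop)
        interface = loop.center[0] - ext + spec.airfluid_fraction * 2.0 * ext
        above = np.broadcast_to(rows < interface, shape)
        img[inside & above] = spec.air_level
        img[inside & ~above] = loop.lumen_level
        truth[inside] = LUMEN

    if spec.lesion is not None:
        les = spec.lesion
        outer = ellipse_mask(shape, les.center, les.semi_axes, les.angle)
        img[outer] = les.level
        if les.wall_thickness > 0:
            t = les.wall_thickness
            inner = ellipse_mask(
                shape,
                les.center,
                (max(les.semi_axes[0] - t, 0.0), max(les.semi_axes[1] - t, 0.0)),
                les.angle,
            )
            wall_level = les.wall_level
            if wall_level is None:
                wall_level = max(les.level - 0.2, 0.05)
            img[outer & ~inner] = wall_level
        truth[outer] = LESION

    if spec.noise_sd > 0:
        rng = as_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    return LabeledImagePair(image=GrayImage(img), truth=LabelMask(truth), spec=spec, seed=seed)


def class_template(
    class_label: int, height: int = 96, width: int = 96, noise_sd: float = 0.05
) -> PhantomSpec:
    """Parameter template for one of the four category archetypes.

    The archetypes differ in loop count/size/orientation and in lesion
    geometry and intensity, so that both the pixel-level segmentation and
    the case-level recognition metric have signal to find.
    """
    h, w = float(height), float(width)

    def pt(r, c):
        return (r * h, c * w)

    if class_label == 0:  # round mass beside a single loop
        loops = (LoopSpec(center=pt(0.35, 0.33), semi_axes=(0.21 * h, 0.18 * w)),)
        lesion = LesionSpec(
            center=pt(0.70, 0.70), semi_axes=(0.13 * h, 0.13 * w), level=0.45, wall_thickness=2.0
        )
    elif class_label == 1:  # thick-walled irregular mass, tilted loop
        loops = (LoopSpec(center=pt(0.32, 0.50), semi_axes=(0.18 * h, 0.25 * w), angle=0.3),)
        lesion = LesionSpec(
            center=pt(0.72, 0.42),
            semi_axes=(0.14 * h, 0.10 * w),
            angle=0.5,
            level=0.58,
            wall_thickness=3.0,
        )
    elif class_label == 2:  # twin loops with an elongated band lesion
        loops = (
            LoopSpec(center=pt(0.30, 0.27), semi_axes=(0.16 * h, 0.14 * w)),
            LoopSpec(center=pt(0.32, 0.72), semi_axes=(0.14 * h, 0.16 * w)),
        )
        lesion = LesionSpec(
            center=pt(0.72, 0.52), semi_axes=(0.15 * h, 0.07 * w), angle=1.1, level=0.70,
            wall_thickness=1.5,
        )
    elif class_label == 3:  # one large twisted loop, bright compact mass
        loops = (LoopSpec(center=pt(0.38, 0.52), semi_axes=(0.25 * h, 0.19 * w), angle=0.8),)
        lesion = LesionSpec(
            center=pt(0.78, 0.72), semi_axes=(0.11 * h, 0.12 * w), level=0.80, wall_thickness=1.0
        )
    else:
        raise ValidationError(f"class_label must be in [0, {N_CLASSES})")
    return PhantomSpec(
        height=height,
        width=width,
        loops=loops,
        lesion=lesion,
        noise_sd=noise_sd,
        class_label=class_label,
    )


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Small geometric perturbation so set members are not identical."""
    scale = 0.02 * min(spec.height, spec.width)

    def j():
        return float(rng.uniform(-scale, scale))

    loops = tuple(
        replace(
            lp,
            center=(lp.center[0] + j(), lp.center[1] + j()),
            semi_axes=(max(lp.semi_axes[0] + j(), 3.0), max(lp.semi_axes[1] + j(), 3.0)),
            angle=lp.angle + float(rng.uniform(-0.1, 0.1)),
        )
        for lp in spec.loops
    )
    lesion = spec.lesion
    if lesion is not None:
        lesion = replace(
            lesion,
            center=(lesion.center[0] + j(), lesion.center[1] + j()),
            semi_axes=(max(lesion.semi_axes[0] + j(), 3.0), max(lesion.semi_axes[1] + j(), 3.0)),
            angle=lesion.angle + float(rng.uniform(-0.1, 0.1)),
        )
    return replace(spec, loops=loops, lesion=lesion)


def make_phantom_set(
    n_per_class: int,
    template_overrides: dict | None = None,
    seed: int = 0,
    height: int = 96,
    width: int = 96,
    noise_sd: float = 0.05,
    jitter: bool = True,
) -> list[LabeledImagePair]:
    """Generate ``4 * n_per_class`` labeled phantoms, ``n_per_class`` per
    archetype, with per-pair seeds derived deterministically from ``seed``.

    ``template_overrides`` maps PhantomSpec field names to replacement
    values applied to every template (e.g. {"noise_sd": 0.0}).
    """
    if n_per_class < 1:
        raise ValidationError(f"n_per_class must be >= 1, got {n_per_class}")
    overrides = dict(template_overrides or {})
    children = spawn_seeds(seed, N_CLASSES * n_per_class)
    pairs: list[LabeledImagePair] = []
    i = 0
    for c in range(N_CLASSES):
        base = class_template(c, height=height, width=width, noise_sd=noise_sd)
        if overrides:
            base = replace(base, **overrides)
        for _ in range(n_per_class):
            rng = np.random.default_rng(children[i])
            spec = _jitter_spec(base, rng) if jitter else base
            pair_seed = int(rng.integers(0, 2**31 - 1))
            pairs.append(make_phantom(spec, pair_seed))
            i += 1
    return pairs
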