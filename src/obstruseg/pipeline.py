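"""End-to-end segmentation pipeline glue.

Blocks are classified into 2 + n_categories classes (background, lumen, and
one lesion class per phantom category) so that a single block classifier
yields both the 3-label segmentation (lesion classes collapse to label 2)
and the case-level category call (majority over blocks predicted as some
lesion class).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bpnn import BPNNModel, TrainConfig, forward
from .features import FeatureScaler, apply_scaler, feature_matrix, fit_scaler
from .ga import GAConfig, optimize_bpnn
from .graphcut import graphcut_refine
from .images import GrayImage, LabelMask, accumulate_scores, extract_blocks
from .phantoms import N_CLASSES, LabeledImagePair
from .util import ValidationError

__all__ = [
    "PipelineConfig",
    "PipelineModel",
    "block_label",
    "build_block_dataset",
    "train_pipeline",
    "segment_image",
    "evaluate_pipeline",
    "foreground_dice",
]

N_SEG_LABELS = 3  # background / lumen / lesion
N_BLOCK_CLASSES = 2 + N_CLASSES


@dataclass(frozen=True)
class PipelineConfig:
    block_size: int = 16
    overlap_step: int = 8
    n_hidden: int = 6
    use_graphcut: bool = True
    lambda_: float = 2.0
    sigma_: float = 0.1
    balance_classes: bool = True  # oversample rare block classes to parity
    ga: GAConfig = field(default_factory=GAConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


@dataclass(frozen=True)
class PipelineModel:
    model: BPNNModel
    scaler: FeatureScaler
    cfg: PipelineConfig


def block_label(truth_patch: np.ndarray, class_label: int) -> int:
    """Training label of a patch: the truth label at the patch center, with
    lesion blocks tagged by the image's category (segmentation label 2 ->
    block class 2 + category).

    Center-pixel labeling keeps boundary-straddling blocks informative:
    the averaged probability map then tracks the geometry at roughly the
    overlap-step resolution instead of eroding thin structures the way a
    majority label does.
    """
    b2 = truth_patch.shape[0] // 2
    lab = int(truth_patch[b2, truth_patch.shape[1] // 2])
    return 2 + class_label if lab == 2 else lab


def build_block_dataset(pairs: list[LabeledImagePair], cfg: PipelineConfig):
    """(features, block class labels) over all blocks of all pairs."""
    feats, labels = [], []
    for pair in pairs:
        grid = extract_blocks(pair.image, cfg.block_size, cfg.overlap_step)
        feats.append(feature_matrix(grid.blocks))
        b = cfg.block_size
        for r, c in grid.origins:
            patch = pair.truth.labels[r : r + b, c : c + b]
            labels.append(block_label(patch, pair.spec.class_label))
    return np.vstack(feats), np.asarray(labels, dtype=np.int64)


def train_pipeline(pairs: list[LabeledImagePair], cfg: PipelineConfig) -> PipelineModel:
    """Fit the scaler and the GA-initialised block classifier."""
    if not pairs:
        raise ValidationError("no training pairs")
    X, y = build_block_dataset(pairs, cfg)
    scaler = fit_scaler(X)
    if cfg.balance_classes:
        # background blocks dwarf lesion blocks; resample to parity so the
        # squared-error training signal is not swamped by the majority class
        rng = np.random.default_rng(cfg.ga.seed)
        target = int(np.bincount(y, minlength=N_BLOCK_CLASSES).max())
        idx = np.concatenate(
            [
                rng.choice(np.where(y == c)[0], size=target, replace=True)
                for c in range(N_BLOCK_CLASSES)
                if np.any(y == c)
            ]
        )
        X, y = X[idx], y[idx]
    Xs = apply_scaler(scaler, X)
    Y = np.eye(N_BLOCK_CLASSES)[y]
    model, _, _ = optimize_bpnn(
        Xs, Y, (X.shape[1], cfg.n_hidden, N_BLOCK_CLASSES), cfg.ga, cfg.train
    )
    return PipelineModel(model=model, scaler=scaler, cfg=cfg)


def _collapse_probs(probs6: np.ndarray) -> np.ndarray:
    """(H, W, 2 + n_categories) -> (H, W, 3): lesion classes pool into one."""
    out = np.empty(probs6.shape[:2] + (N_SEG_LABELS,))
    out[:, :, 0] = probs6[:, :, 0]
    out[:, :, 1] = probs6[:, :, 1]
    out[:, :, 2] = probs6[:, :, 2:].sum(axis=2)
    s = out.sum(axis=2, keepdims=True)
    return out / np.clip(s, 1e-12, None)


def segment_image(pmodel: PipelineModel, image: GrayImage):
    """Segment one image.

    Returns (mask, category, probs3): a 3-label mask, the case-level
    category call (majority over blocks predicted as a lesion class, with a
    summed-probability fallback), and the per-pixel 3-class probability map.
    """
    cfg = pmodel.cfg
    grid = extract_blocks(image, cfg.block_size, cfg.overlap_step)
    feats = apply_scaler(pmodel.scaler, feature_matrix(grid.blocks))
    scores = forward(pmodel.model, feats)  # (n_blocks, N_BLOCK_CLASSES)
    norm = scores / np.clip(scores.sum(axis=1, keepdims=True), 1e-12, None)

    block_pred = np.argmax(norm, axis=1)
    lesion_blocks = block_pred[block_pred >= 2] - 2
    if len(lesion_blocks):
        category = int(np.argmax(np.bincount(lesion_blocks, minlength=N_CLASSES)))
    else:
        category = int(np.argmax(norm[:, 2:].sum(axis=0)))

    probs6 = accumulate_scores(grid, norm)
    probs3 = _collapse_probs(probs6)
    if cfg.use_graphcut:
        mask = graphcut_refine(image, probs3, lambda_=cfg.lambda_, sigma_=cfg.sigma_)
    else:
        mask = LabelMask(np.argmax(probs3, axis=2).astype(np.int64))
    return mask, category, probs3


def foreground_dice(pred: LabelMask, truth: LabelMask) -> float:
    """Dice of the binary foreground (any non-background label)."""
    p = pred.labels > 0
    t = truth.labels > 0
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(p & t) / denom)


def evaluate_pipeline(pmodel: PipelineModel, pairs: list[LabeledImagePair]) -> dict:
    """Per-image segmentation metrics plus case-level recognition rates."""
    from .evaluate import recognition_rate, seg_metrics

    per_image = []
    cats, cat_truth = [], []
    for pair in pairs:
        mask, category, _ = segment_image(pmodel, pair.image)
        m = seg_metrics(mask, pair.truth, labels=range(N_SEG_LABELS))
        per_image.append(
            {
                "pixel_accuracy": m.pixel_accuracy,
                "fg_dice": foreground_dice(mask, pair.truth),
                "dice": m.dice,
                "category_pred": category,
                "category_truth": pair.spec.class_label,
            }
        )
        cats.append(category)
        cat_truth.append(pair.spec.class_label)
    return {
        "per_image": per_image,
        "mean_pixel_accuracy": float(np.mean([r["pixel_accuracy"] for r in per_image])),
        "mean_fg_dice": float(np.mean([r["fg_dice"] for r in per_image])),
        "recognition": recognition_rate(cats, cat_truth, n_categories=N_CLASSES),
    }
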