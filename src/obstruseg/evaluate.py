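"""Segmentation metrics, per-category recognition rates, and the two
parameter sweeps (hidden-layer size cross-validation; block size / overlap
step grid)."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .bpnn import TrainConfig, predict_labels
from .ga import GAConfig, optimize_bpnn
from .images import LabelMask
from .util import ValidationError, as_rng

__all__ = [
    "SegMetrics",
    "SweepResult",
    "seg_metrics",
    "recognition_rate",
    "stratified_folds",
    "hl_sweep",
    "block_param_sweep",
]


@dataclass(frozen=True)
class SegMetrics:
    pixel_accuracy: float
    dice: dict  # class label -> Dice in [0, 1]
    iou: dict  # class label -> IoU in [0, 1]
    confusion: np.ndarray  # (K, K) counts, rows = truth, cols = prediction
    labels: tuple


def seg_metrics(pred: LabelMask, truth: LabelMask, labels=None) -> SegMetrics:
    """Pixel accuracy, per-class Dice/IoU and the confusion matrix.

    Dice of a class absent from both masks is defined as 1.
    """
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {truth.shape}")
    p = pred.labels.ravel()
    t = truth.labels.ravel()
    if labels is None:
        labels = tuple(sorted(set(np.unique(p)) | set(np.unique(t))))
    labels = tuple(int(l) for l in labels)
    K = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    conf = np.zeros((K, K), dtype=np.int64)
    for lab_t in labels:
        sel = t == lab_t
        for lab_p in labels:
            conf[index[lab_t], index[lab_p]] = int(np.sum(sel & (p == lab_p)))
    acc = float(np.trace(conf)) / max(conf.sum(), 1)
    dice, iou = {}, {}
    for lab in labels:
        np_, nt = np.sum(p == lab), np.sum(t == lab)
        inter = np.sum((p == lab) & (t == lab))
        union = np_ + nt - inter
        if np_ + nt == 0:
            dice[lab], iou[lab] = 1.0, 1.0
        else:
            dice[lab] = 2.0 * inter / (np_ + nt)
            iou[lab] = inter / union if union else 1.0
    return SegMetrics(pixel_accuracy=acc, dice=dice, iou=iou, confusion=conf, labels=labels)


def recognition_rate(case_preds, case_truth, n_categories: int = 4) -> dict:
    """Per-category fraction of correctly recognised cases.

    A category with no cases gets rate None (never silently 0); the macro
    average runs over the defined categories only.
    """
    preds = np.asarray(case_preds)
    truth = np.asarray(case_truth)
    if preds.shape != truth.shape:
        raise ValidationError("prediction/truth length mismatch")
    rates: dict = {}
    defined = []
    for c in range(n_categories):
        sel = truth == c
        if not np.any(sel):
            rates[c] = None
            continue
        rates[c] = float(np.mean(preds[sel] == c))
        defined.append(rates[c])
    rates["macro"] = float(np.mean(defined)) if defined else None
    return rates


def stratified_folds(y: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified k-fold index partition."""
    y = np.asarray(y)
    rng = as_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        if len(idx) < k:
            raise ValidationError(f"class {cls} has {len(idx)} samples < {k} folds")
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    return [np.array(sorted(f), dtype=np.int64) for f in folds]


@dataclass
class SweepResult:
    rows: list[dict] = field(default_factory=list)
    seed: int = 0

    def best(self, key: str = "mean_accuracy") -> dict:
        return max(self.rows, key=lambda r: r[key])


def hl_sweep(
    X: np.ndarray,
    y: np.ndarray,
    hidden_counts=(2, 3, 4, 5, 6, 7, 8),
    k_folds: int = 5,
    ga_cfg: GAConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> SweepResult:
    """Cross-validated block-classification accuracy per hidden-node count."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.int64)
    n_out = int(y.max()) + 1
    Y = np.eye(n_out)[y]
    folds = stratified_folds(y, k_folds, seed=seed)
    ga_cfg = ga_cfg or GAConfig(seed=seed)
    train_cfg = train_cfg or TrainConfig(seed=seed)
    result = SweepResult(seed=seed)
    for nh in hidden_counts:
        accs = []
        for i, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(X)), val_idx)
            model, _, _ = optimize_bpnn(
                X[train_idx], Y[train_idx], (X.shape[1], nh, n_out), ga_cfg, train_cfg
            )
            accs.append(float(np.mean(predict_labels(model, X[val_idx]) == y[val_idx])))
        result.rows.append(
            {
                "n_hidden": int(nh),
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs)),
                "fold_accuracies": accs,
            }
        )
    return result


def block_param_sweep(pairs, block_sizes, overlap_steps, pipeline_cfg=None) -> SweepResult:
    """Grid of (block size, overlap step) -> segmentation metrics and
    wall-clock time.  Times are informational output only; invalid pairs are
    skipped with a warning."""
    import logging

    from .pipeline import PipelineConfig, evaluate_pipeline, train_pipeline

    logger = logging.getLogger(__name__)
    cfg = pipeline_cfg or PipelineConfig()
    result = SweepResult()
    min_side = min(min(p.image.height, p.image.width) for p in pairs)
    for b in block_sizes:
        for s in overlap_steps:
            if not (1 <= s <= b <= min_side):
                logger.warning("skipping invalid (block=%d, step=%d)", b, s)
                continue
            from dataclasses import replace

            run_cfg = replace(cfg, block_size=b, overlap_step=s)
            t0 = time.perf_counter()
            model = train_pipeline(pairs, run_cfg)
            report = evaluate_pipeline(model, pairs)
            elapsed = time.perf_counter() - t0
            n_blocks_axis_r = len(range(0, min_side - b + 1, s))
            result.rows.append(
                {
                    "block_size": b,
                    "overlap_step": s,
                    "mean_accuracy": report["mean_pixel_accuracy"],
                    "mean_fg_dice": report["mean_fg_dice"],
                    "macro_recognition": report["recognition"]["macro"],
                    "wall_time_s": elapsed,
                }
            )
    return result
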