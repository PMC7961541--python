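"""Segmentation evaluation: precision, recall, F1 and mean IoU, with the
per-image mean +/- standard-deviation aggregation used for validation
reporting.

Degenerate denominators (e.g. precision on an image with no predicted
foreground) yield ``nan`` — an explicit undefined marker — and are
excluded from dataset averages rather than silently counted as 0 or 1,
so negative images with empty predictions do not distort the means.
Mean IoU averages the per-class intersection-over-union over the two
actual classes (background, coral); a class absent from both prediction
and ground truth is skipped.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_counts",
           "precision", "recall", "f1_score", "mean_iou", "image_metrics",
           "evaluate_pairs", "evaluate_dataset"]


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_masks(pred: np.ndarray, gt: np.ndarray):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return pred.astype(bool), gt.astype(bool)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    pred, gt = _check_masks(pred, gt)
    return ConfusionCounts(
        tp=int(np.sum(pred & gt)),
        fp=int(np.sum(pred & ~gt)),
        fn=int(np.sum(~pred & gt)),
        tn=int(np.sum(~pred & ~gt)),
    )


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); nan when nothing was predicted positive."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else float("nan")


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); nan when the ground truth has no positives."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else float("nan")


def f1_score(pr: float, re: float) -> float:
    """Harmonic mean 2*PR*RE/(PR+RE); 0 when both are 0, nan if either
    input is undefined."""
    if np.isnan(pr) or np.isnan(re):
        return float("nan")
    return 2 * pr * re / (pr + re) if pr + re else 0.0


def mean_iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Per-class IoU averaged over background and coral; classes absent
    from both masks are skipped."""
    pred, gt = _check_masks(pred, gt)
    ious = []
    for cls in (False, True):
        p = pred == cls
        g = gt == cls
        union = np.sum(p | g)
        if union == 0:
            continue
        ious.append(np.sum(p & g) / union)
    if not ious:
        return float("nan")
    return float(np.mean(ious))


def image_metrics(pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    c = confusion_counts(pred, gt)
    pr = precision(c)
    re = recall(c)
    return {"precision": pr, "recall": re, "f1": f1_score(pr, re),
            "mean_iou": mean_iou(pred, gt)}


_METRIC_NAMES = ("precision", "recall", "f1", "mean_iou")


@dataclasses.dataclass
class MetricsReport:
    """Per-image metrics plus their mean and (population) standard
    deviation across validation images, all on the [0, 1] scale."""

    per_image: pd.DataFrame
    mean: dict[str, float]
    std: dict[str, float]

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.mean.items()}

    def to_json(self, path) -> None:
        payload = {
            "mean_percent": self.as_percent(),
            "std_percent": {k: 100.0 * v for k, v in self.std.items()},
            "n_images": int(len(self.per_image)),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path) -> None:
        table = self.per_image.copy()
        for name in _METRIC_NAMES:
            table[name] = 100.0 * table[name]
        table.to_csv(path, index=False)


def evaluate_pairs(pairs, ids=None) -> MetricsReport:
    """Macro aggregation of (pred, gt) mask pairs: metrics per image,
    then nan-excluding mean and population std over images."""
    rows = []
    for i, (pred, gt) in enumerate(pairs):
        row = {"image_id": ids[i] if ids is not None else i}
        row.update(image_metrics(pred, gt))
        rows.append(row)
    if not rows:
        raise ValueError("no image pairs to evaluate")
    df = pd.DataFrame(rows)
    mean, std = {}, {}
    for name in _METRIC_NAMES:
        vals = df[name].to_numpy()
        defined = vals[~np.isnan(vals)]
        # a metric undefined on every image stays an undefined marker
        mean[name] = float(defined.mean()) if defined.size else float("nan")
        std[name] = float(defined.std()) if defined.size else float("nan")
    return MetricsReport(per_image=df, mean=mean, std=std)


def evaluate_dataset(model, records) -> MetricsReport:
    """Run a fitted segmenter over manifest records and aggregate.

    ``model`` is anything with a ``predict(images) -> masks`` method (a
    fitted ``CoralSegmenter``) or a callable; every record must carry a
    mask path.
    """
    from .preprocess import load_gray_image, load_mask

    records = list(records)
    if not records:
        raise ValueError("empty validation manifest")
    missing = [r.image_path for r in records if not r.mask_path]
    if missing:
        raise ValueError(f"records without masks: {missing[:3]}")
    images = np.stack([load_gray_image(r.image_path) for r in records])
    gts = [load_mask(r.mask_path) for r in records]
    predict = model.predict if hasattr(model, "predict") else model
    preds = predict(images)
    return evaluate_pairs(zip(preds, gts),
                          ids=[Path(r.image_path).name for r in records])
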