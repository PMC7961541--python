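"""Training procedure: loss, learning-rate schedule and the two phases
(backbone pre-training as an image-level classifier, then full
segmentation training).

The heavy lifting lives in the estimator classes
(:mod:`coralseg.estimators`); the functions here are the thin
manifest-level entry points plus the pieces shared by both phases.

Full-scale defaults: pre-training runs 200 epochs at batch size 32,
segmentation 150 epochs at batch size 16, both with Adam at an initial
rate of 1e-4 decayed by a factor 0.99 per epoch, 90/10 train/validation
split, and 50%-probability rotation/flip augmentation on the training
split only.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import ModelConfig
from .nn import Tensor, ops
from .nn.optim import lr_at_epoch  # noqa: F401  (re-exported schedule)
from .preprocess import load_gray_image, load_mask

__all__ = ["TrainConfig", "cross_entropy_loss", "lr_at_epoch",
           "pretrain_backbone", "train_segmentation", "load_arrays"]


@dataclasses.dataclass
class TrainConfig:
    """Optimisation settings for one training run."""

    epochs: int = 150
    batch_size: int = 16
    v0: float = 1e-4
    alpha: float = 0.99
    seed: int = 0
    augment: bool = True
    phase: str = "segment"

    def __post_init__(self):
        if self.phase not in ("pretrain", "segment"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    @classmethod
    def pretrain(cls, **overrides) -> "TrainConfig":
        base = dict(epochs=200, batch_size=32, phase="pretrain")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def segment(cls, **overrides) -> "TrainConfig":
        base = dict(epochs=150, batch_size=16, phase="segment")
        base.update(overrides)
        return cls(**base)


def cross_entropy_loss(logits, target, *, reduction: str = "mean") -> float:
    """Mean softmax cross-entropy between 2-channel scores and integer
    class targets.

    ``logits`` is (N, 2, H, W) (or (2, H, W) for one image, or (N, 2)
    for image-level classification); ``target`` holds class ids of the
    matching shape without the channel axis.  The per-pixel terms
    -log p(true class) are averaged over all pixels and images
    (``reduction="mean"``) or summed (``"sum"``).
    """
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    target = np.asarray(target)
    if arr.ndim == 3:
        arr = arr[None]
        target = target[None]
    if arr.shape[0] != target.shape[0] or arr.shape[2:] != target.shape[1:]:
        raise ValueError(
            f"logits {arr.shape} incompatible with target {target.shape}")
    loss = ops.softmax_cross_entropy(Tensor(arr), target.astype(np.int64),
                                     reduction=reduction)
    return float(loss.data)


def load_arrays(records, *, need_masks: bool = False):
    """Stack manifest records into (images, masks | None, labels)."""
    records = list(records)
    if not records:
        raise ValueError("no records to load")
    images = np.stack([load_gray_image(r.image_path) for r in records])
    labels = np.array([r.image_label for r in records], dtype=np.int64)
    masks = None
    if need_masks:
        missing = [r.image_path for r in records if not r.mask_path]
        if missing:
            raise ValueError(f"records without masks: {missing[:3]}")
        masks = np.stack([load_mask(r.mask_path) for r in records])
    return images, masks, labels


def _split_records(records):
    train = [r for r in records if r.split == "train"]
    val = [r for r in records if r.split == "val"]
    if not train:
        raise ValueError("manifest has no training records")
    return train, val


def pretrain_backbone(records, config: TrainConfig | None = None,
                      model_config: ModelConfig | None = None):
    """Pre-train the backbone as an image-level coral/no-coral
    classifier on a manifest; returns the fitted
    :class:`~coralseg.estimators.CoralPresenceClassifier` (loss curves
    in ``.history_``, backbone in ``.net_.backbone``)."""
    from .estimators import CoralPresenceClassifier

    config = config or TrainConfig.pretrain()
    train, val = _split_records(records)
    xt, _, yt = load_arrays(train)
    validation = None
    if val:
        xv, _, yv = load_arrays(val)
        validation = (xv, yv)
    clf = CoralPresenceClassifier(
        model_config=model_config, epochs=config.epochs,
        batch_size=config.batch_size, learning_rate=config.v0,
        decay=config.alpha, augment=config.augment, seed=config.seed,
        val_fraction=0.0 if validation else 0.1)
    clf.fit(xt, yt, validation_data=validation)
    return clf


def train_segmentation(records, config: TrainConfig | None = None,
                       model_config: ModelConfig | None = None,
                       init=None, checkpoint_dir=None):
    """Train the full segmentation network on a manifest with pixel
    masks; ``init`` is an optional pre-trained classifier (or backbone
    state dict) to warm-start the encoder.  Returns the fitted
    :class:`~coralseg.estimators.CoralSegmenter`."""
    from .estimators import CoralSegmenter

    config = config or TrainConfig.segment()
    train, val = _split_records(records)
    xt, mt, _ = load_arrays(train, need_masks=True)
    validation = None
    if val:
        xv, mv, _ = load_arrays(val, need_masks=True)
        validation = (xv, mv)
    seg = CoralSegmenter(
        model_config=model_config, epochs=config.epochs,
        batch_size=config.batch_size, learning_rate=config.v0,
        decay=config.alpha, augment=config.augment, seed=config.seed,
        backbone_init=init, checkpoint_dir=checkpoint_dir,
        val_fraction=0.0 if validation else 0.1)
    seg.fit(xt, mt, validation_data=validation)
    return seg
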