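"""Scikit-learn style estimators wrapping the network and its training.

* :class:`CoralPresenceClassifier` — backbone + GAP + linear head,
  trained on image-level coral/no-coral labels (the pre-training phase).
* :class:`CoralSegmenter` — the full encoder-decoder, trained on pixel
  masks; optionally warm-started from a fitted presence classifier.
* :class:`CoralActivationMapper` — a class-activation-map head on the
  frozen segmenter's fused decoder features; ``transform`` returns
  per-pixel coral-evidence maps normalised to [0, 100] %.

All three follow the sklearn contract: constructor stores
hyperparameters untouched, ``fit`` validates input and sets
trailing-underscore attributes, ``get_params``/``set_params``/``clone``
work out of the box.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from . import cam as cam_mod
from . import nn
from .metrics import mean_iou
from .model import (ClassifierNet, DeeperLabC, ModelConfig, predict_mask,
                    save_checkpoint)
from .nn import Adam, Tensor, lr_at_epoch, no_grad, ops
from .preprocess import augment_pair

__all__ = ["CoralPresenceClassifier", "CoralSegmenter",
           "CoralActivationMapper"]


def _validate_images(X, *, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 4 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 3:
        raise ValueError(f"{name} must be (n_samples, height, width), "
                         f"got shape {X.shape}")
    n, h, w = X.shape
    if h % 16 or w % 16:
        raise ValueError(f"image sides must be divisible by 16, got {h}x{w}")
    if not np.isfinite(X).all():
        raise ValueError(f"{name} contains non-finite values")
    return X


def _validate_masks(y, X) -> np.ndarray:
    y = np.asarray(y)
    if y.shape != X.shape:
        raise ValueError(f"masks shape {y.shape} must match images {X.shape}")
    vals = np.unique(y)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError(f"masks must be binary, found values {vals[:5]}")
    return y.astype(np.int64)


def _holdout_split(n: int, fraction: float, seed: int):
    if fraction <= 0 or n < 2:
        return np.arange(n), np.array([], dtype=int)
    rng = np.random.default_rng([seed, 0x5F])
    order = rng.permutation(n)
    n_val = max(1, int(round(n * fraction)))
    return np.sort(order[n_val:]), np.sort(order[:n_val])


def _batches(n: int, batch_size: int, rng: np.random.Generator | None):
    idx = rng.permutation(n) if rng is not None else np.arange(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def _resolved_config(model_config, seed: int) -> ModelConfig:
    cfg = model_config if model_config is not None else ModelConfig()
    return dataclasses.replace(cfg, seed=seed)


class _TrainerMixin:
    """Shared Adam/schedule training loop over image batches."""

    def _fit_loop(self, net, x_train, t_train, x_val, t_val, *,
                  segment: bool, checkpoint_dir=None, cfg=None):
        opt = Adam(net.parameters(), lr=self.learning_rate)
        rng_shuffle = np.random.default_rng([self.seed, 0x10])
        rng_aug = np.random.default_rng([self.seed, 0x20])
        history = []
        for epoch in range(self.epochs):
            opt.lr = lr_at_epoch(self.learning_rate, self.decay, epoch)
            net.train()
            total, count = 0.0, 0
            for bidx in _batches(len(x_train), self.batch_size, rng_shuffle):
                xb = x_train[bidx]
                tb = t_train[bidx]
                if self.augment:
                    xb = np.array(xb)
                    tb = np.array(tb)
                    for i in range(len(bidx)):
                        if segment:
                            xb[i], tb[i] = augment_pair(xb[i], tb[i], rng_aug)
                        else:
                            xb[i], _ = augment_pair(xb[i], None, rng_aug)
                logits = net(Tensor(xb[:, None].astype(np.float32)))
                loss = ops.softmax_cross_entropy(logits, tb)
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * len(bidx)
                count += len(bidx)
            row = {"epoch": epoch, "lr": opt.lr, "train_loss": total / count}
            if len(x_val):
                val_loss, val_metric = self._evaluate(net, x_val, t_val,
                                                      segment=segment)
                row["val_loss"] = val_loss
                row["val_miou" if segment else "val_accuracy"] = val_metric
            history.append(row)
            if checkpoint_dir is not None:
                save_checkpoint(Path(checkpoint_dir) / f"epoch_{epoch:04d}.npz",
                                net, cfg, seed=self.seed,
                                extra={"epoch": epoch})
        net.eval()
        return pd.DataFrame(history)

    def _evaluate(self, net, x, t, *, segment: bool):
        net.eval()
        losses, metrics, weights = [], [], []
        with no_grad():
            for bidx in _batches(len(x), self.batch_size, None):
                logits = net(Tensor(x[bidx][:, None].astype(np.float32)))
                loss = ops.softmax_cross_entropy(logits, t[bidx])
                losses.append(float(loss.data) * len(bidx))
                weights.append(len(bidx))
                if segment:
                    preds = predict_mask(logits)
                    metrics.extend(mean_iou(p, g)
                                   for p, g in zip(preds, t[bidx]))
                else:
                    pred = logits.data.argmax(axis=1)
                    metrics.extend((pred == t[bidx]).astype(float))
        return (float(np.sum(losses) / np.sum(weights)),
                float(np.nanmean(metrics)))


class CoralPresenceClassifier(_TrainerMixin, ClassifierMixin, BaseEstimator):
    """Image-level coral/no-coral classifier used to pre-train the
    segmentation backbone.

    Defaults follow the full-scale pre-training recipe (200 epochs,
    batch 32, Adam at 1e-4 with 0.99 per-epoch decay, 90/10 split,
    augmentation on the training split only); pass
    ``model_config=ModelConfig.desk()`` and smaller epochs for CPU-scale
    runs.
    """

    def __init__(self, model_config=None, epochs=200, batch_size=32,
                 learning_rate=1e-4, decay=0.99, augment=True,
                 val_fraction=0.1, seed=0):
        self.model_config = model_config
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.decay = decay
        self.augment = augment
        self.val_fraction = val_fraction
        self.seed = seed

    def fit(self, X, y, validation_data=None):
        X = _validate_images(X)
        y = np.asarray(y, dtype=np.int64)
        if y.shape != (len(X),):
            raise ValueError("y must be one binary label per image")
        if len(X) == 0:
            raise ValueError("empty training set")
        cfg = _resolved_config(self.model_config, self.seed)
        net = ClassifierNet(cfg)
        if validation_data is not None:
            xv = _validate_images(validation_data[0], name="validation X")
            yv = np.asarray(validation_data[1], dtype=np.int64)
            xt, yt = X, y
        else:
            tr, va = _holdout_split(len(X), self.val_fraction, self.seed)
            xt, yt = X[tr], y[tr]
            xv, yv = X[va], y[va]
        if len(xt) == 0:
            raise ValueError("empty training split")
        self.model_config_ = cfg
        self.classes_ = np.array([0, 1])
        self.net_ = net
        self.history_ = self._fit_loop(net, xt, yt, xv, yv, segment=False)
        return self

    def decision_scores(self, X) -> np.ndarray:
        X = _validate_images(X)
        out = []
        with no_grad():
            for bidx in _batches(len(X), self.batch_size, None):
                logits = self.net_(Tensor(X[bidx][:, None].astype(np.float32)))
                out.append(logits.data)
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        return ops.softmax(self.decision_scores(X), axis=1)

    def predict(self, X) -> np.ndarray:
        return self.decision_scores(X).argmax(axis=1)

    def backbone_state(self) -> dict[str, np.ndarray]:
        return self.net_.backbone.state_dict()


class CoralSegmenter(_TrainerMixin, BaseEstimator):
    """The full coral segmentation network as a fit/predict estimator.

    ``fit(X, masks)`` trains with per-pixel cross-entropy;
    ``predict(X)`` returns binary coral masks; ``score(X, masks)`` is
    the mean per-image IoU averaged over the two classes.  Defaults are
    the full-scale segmentation recipe (150 epochs, batch 16, Adam at
    1e-4 with 0.99 decay).
    """

    def __init__(self, model_config=None, epochs=150, batch_size=16,
                 learning_rate=1e-4, decay=0.99, augment=True,
                 val_fraction=0.1, backbone_init=None, checkpoint_dir=None,
                 seed=0):
        self.model_config = model_config
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.decay = decay
        self.augment = augment
        self.val_fraction = val_fraction
        self.backbone_init = backbone_init
        self.checkpoint_dir = checkpoint_dir
        self.seed = seed

    def _load_backbone(self, net: DeeperLabC):
        src = self.backbone_init
        if src is None:
            return
        if isinstance(src, CoralPresenceClassifier):
            state = src.backbone_state()
        elif hasattr(src, "state_dict"):
            state = src.state_dict()
        elif isinstance(src, (str, Path)):
            with np.load(src) as archive:
                state = {k: archive[k] for k in archive.files}
            state = {k.removeprefix("backbone."): v for k, v in state.items()
                     if k.startswith("backbone.")} or state
        else:
            state = dict(src)
        net.backbone.load_state_dict(state)

    def fit(self, X, y, validation_data=None):
        X = _validate_images(X)
        y = _validate_masks(y, X)
        cfg = _resolved_config(self.model_config, self.seed)
        net = DeeperLabC(cfg)
        self._load_backbone(net)
        if validation_data is not None:
            xv = _validate_images(validation_data[0], name="validation X")
            yv = _validate_masks(validation_data[1], xv)
            xt, yt = X, y
        else:
            tr, va = _holdout_split(len(X), self.val_fraction, self.seed)
            xt, yt = X[tr], y[tr]
            xv, yv = X[va], y[va]
        if len(xt) == 0:
            raise ValueError("empty training split")
        self.model_config_ = cfg
        self.net_ = net
        self.history_ = self._fit_loop(net, xt, yt, xv, yv, segment=True,
                                       checkpoint_dir=self.checkpoint_dir,
                                       cfg=cfg)
        return self

    def decision_logits(self, X) -> np.ndarray:
        X = _validate_images(X)
        out = []
        with no_grad():
            for bidx in _batches(len(X), self.batch_size, None):
                logits = self.net_(Tensor(X[bidx][:, None].astype(np.float32)))
                out.append(logits.data)
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        return predict_mask(self.decision_logits(X))

    def score(self, X, y) -> float:
        X = _validate_images(X)
        y = _validate_masks(y, X)
        preds = self.predict(X)
        return float(np.nanmean([mean_iou(p, g) for p, g in zip(preds, y)]))

    def features(self, X) -> np.ndarray:
        """Fused decoder feature maps (stride 16) — the tap point for the
        class-activation head."""
        X = _validate_images(X)
        out = []
        with no_grad():
            for bidx in _batches(len(X), self.batch_size, None):
                _, fused = self.net_(Tensor(X[bidx][:, None].astype(np.float32)),
                                     return_features=True)
                out.append(fused.data)
        return np.concatenate(out)


class CoralActivationMapper(TransformerMixin, BaseEstimator):
    """Class-activation-map head on a frozen, fitted segmenter.

    ``fit(X, labels)`` trains a 1x1 convolution producing the non-coral
    and coral response maps N0, N1, whose spatial means G0, G1 are
    weighted by scalar class weights (w0, w1) into image-level scores,
    against image-level cross-entropy.  Only the head parameters are
    updated; the segmenter's weights stay frozen.  ``transform`` returns
    per-pixel coral-evidence maps at input resolution, normalised to
    [0, 100] %.
    """

    def __init__(self, segmenter=None, epochs=200, batch_size=32,
                 learning_rate=1e-4, decay=0.99, seed=0):
        self.segmenter = segmenter
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.decay = decay
        self.seed = seed

    def fit(self, X, y):
        if self.segmenter is None or not hasattr(self.segmenter, "net_"):
            raise ValueError("segmenter must be a fitted CoralSegmenter")
        X = _validate_images(X)
        y = np.asarray(y, dtype=np.int64)
        feats = self.segmenter.features(X).astype(np.float32)
        c_feat = feats.shape[1]
        rng = np.random.default_rng([self.seed, 0xCA])
        conv_w = nn.Parameter(rng.normal(0.0, np.sqrt(2.0 / c_feat),
                                         (2, c_feat, 1, 1)).astype(np.float32))
        # class scores are a full linear map of the pooled means
        # (G0, G1); the coral row supplies the scalar weights (w0, w1)
        # that also combine the response maps into the activation map
        w = nn.Parameter(rng.normal(0.0, 1.0, (2, 2)).astype(np.float32))
        b = nn.Parameter(np.zeros(2, dtype=np.float32))
        opt = Adam([conv_w, w, b], lr=self.learning_rate)
        rng_shuffle = np.random.default_rng([self.seed, 0xCB])
        history = []
        for epoch in range(self.epochs):
            opt.lr = lr_at_epoch(self.learning_rate, self.decay, epoch)
            total, count = 0.0, 0
            for bidx in _batches(len(feats), self.batch_size, rng_shuffle):
                f = Tensor(feats[bidx])
                maps = ops.conv2d(f, conv_w)
                g = ops.flatten2d(ops.global_avg_pool(maps))
                scores = ops.linear(g, w, b)
                loss = ops.softmax_cross_entropy(scores, y[bidx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * len(bidx)
                count += len(bidx)
            history.append({"epoch": epoch, "lr": opt.lr,
                            "train_loss": total / count})
        self.conv_weight_ = conv_w.data
        self.linear_weight_ = w.data.copy()
        self.class_weights_ = w.data[1].copy()  # (w0, w1): the coral row
        self.class_bias_ = b.data.copy()
        self.history_ = pd.DataFrame(history)
        return self

    def _maps(self, X):
        feats = self.segmenter.features(X)
        n0, n1, scores = cam_mod.cam_head_forward(
            feats, self.conv_weight_, self.linear_weight_, self.class_bias_)
        return n0, n1, scores

    def decision_scores(self, X) -> np.ndarray:
        return self._maps(X)[2]

    def predict(self, X) -> np.ndarray:
        return self.decision_scores(X).argmax(axis=1)

    def transform(self, X) -> np.ndarray:
        """Normalised coral-evidence maps, (n, H, W) in [0, 100] %."""
        X = _validate_images(X)
        n0, n1, _ = self._maps(X)
        raw = cam_mod.compute_cam(n0, n1, self.class_weights_[0],
                                  self.class_weights_[1])
        h, w = X.shape[1:]
        up = ops.bilinear_resize(Tensor(raw[:, None]), h, w).data[:, 0]
        return cam_mod.normalize_cam(up)
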