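"""The DeeperLabC segmentation network.

An encoder-decoder for binary (coral vs. background) segmentation of
single-channel images:

* **Backbone** — ResNet34 pruned of its final residual stage: a 7x7
  stride-2 stem with batch normalisation and 3x3 stride-2 max pooling
  (low-level features at stride 4), followed by three stages of
  [3, 4, 6] basic residual blocks (``y = F(x) + x``) at widths
  [64, 128, 256].  The residual stages contain 2*(3+4+6) = 26
  convolutions; stages 2-3 halve resolution, so the high-level map sits
  at stride 16 with 256 channels.
* **ASPP** — four parallel dilated 3x3 convolutions (rate 1 realised as
  a 1x1) plus a global-average-pooling branch broadcast back onto the
  grid, concatenated and reduced to 256 channels by a 1x1 convolution.
* **Low-level path** — 1x1 reduction of the stride-4 stem features then
  space-to-depth (r=4) so they align with the stride-16 ASPP output.
* **Decoder** — channel concatenation, two large-kernel (7x7) fusion
  convolutions, a 1x1 prediction convolution to ``2*r^2`` channels,
  depth-to-space (r=4) back to stride 4, and bilinear x4 interpolation
  to full resolution, yielding 2 x H x W class scores.

All widths scale by a single ``width`` multiplier so the same
architecture trains on a laptop CPU at 64x64.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor, ops

__all__ = ["ModelConfig", "Backbone", "ASPP", "DeeperLabC", "ClassifierNet",
           "predict_mask", "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass
class ModelConfig:
    """Hyperparameters of the network; defaults are the full-scale model."""

    in_channels: int = 1
    stem_channels: int = 64
    stage_blocks: tuple[int, ...] = (3, 4, 6)
    stage_channels: tuple[int, ...] = (64, 128, 256)
    aspp_rates: tuple[int, ...] = (1, 6, 12, 18)
    aspp_out_channels: int = 256
    lowlevel_reduced_channels: int = 32
    s2d_block: int = 4
    fusion_kernel: int = 7
    fusion_channels: int = 256
    num_classes: int = 2
    width: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.fusion_kernel % 2 == 0:
            raise ValueError("fusion_kernel must be odd")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")

    def scaled(self, c: int) -> int:
        return max(1, int(round(c * self.width)))

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Quarter-width configuration for CPU-scale training/tests."""
        defaults = dict(width=0.25, lowlevel_reduced_channels=8)
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("stage_blocks", "stage_channels", "aspp_rates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _check_side(side: int) -> None:
    if side % 16:
        raise ValueError(f"input side {side} must be divisible by 16")


class BasicBlock(nn.Module):
    """Residual unit y = F(x) + shortcut(x); F = conv-bn-relu-conv-bn."""

    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator, zero_init_residual: bool = False):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, pad=1, bias=False,
                               rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, stride=1, pad=1, bias=False,
                               rng=rng)
        self.bn2 = nn.BatchNorm2d(cout, zero_init=zero_init_residual)
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, bias=False,
                                  rng=rng)
            self.proj_bn = nn.BatchNorm2d(cout)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        f = ops.relu(self.bn1(self.conv1(x)))
        f = self.bn2(self.conv2(f))
        short = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return ops.relu(ops.add(f, short))

    def residual_conv_count(self) -> int:
        """Convolutions in the residual branch F (projections excluded)."""
        return 2


class Backbone(nn.Module):
    """Pruned ResNet34: stem to stride 4, three residual stages to stride 16."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 zero_init_residual: bool = False):
        super().__init__()
        self.cfg = cfg
        stem = cfg.scaled(cfg.stem_channels)
        self.stem_conv = nn.Conv2d(cfg.in_channels, stem, 7, stride=2, pad=3,
                                   bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem)
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.stages = []
        cin = stem
        for i, (blocks, ch) in enumerate(zip(cfg.stage_blocks,
                                             cfg.stage_channels)):
            cout = cfg.scaled(ch)
            stage = []
            for b in range(blocks):
                stride = 2 if (i > 0 and b == 0) else 1
                stage.append(BasicBlock(cin, cout, stride, rng,
                                        zero_init_residual))
                cin = cout
            self.stages.append(nn.Sequential(*stage))
        self.out_channels = cin
        self.lowlevel_channels = stem

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (low-level stride-4 map, high-level stride-16 map)."""
        x = ops.relu(self.stem_bn(self.stem_conv(x)))
        low = self.pool(x)
        h = low
        for stage in self.stages:
            h = stage(h)
        return low, h

    def residual_conv_count(self) -> int:
        """Number of convolutions inside the residual branches of all
        basic blocks (stem and 1x1 shortcut projections excluded)."""
        return sum(block.residual_conv_count()
                   for stage in self.stages for block in stage.layers)


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling with a global-average branch.

    Rate-1 is realised as a 1x1 convolution; each dilated branch and the
    final 1x1 reduction carry batch normalisation + ReLU.  The pooled
    branch skips batch normalisation (its 1x1 spatial extent makes batch
    statistics degenerate at small batch sizes) and is broadcast back to
    the grid by bilinear interpolation, which for a 1x1 source is an
    exact constant fill.
    """

    def __init__(self, cin: int, cout: int, rates: tuple[int, ...],
                 rng: np.random.Generator):
        super().__init__()
        self.rates = tuple(rates)
        self.branches = []
        for rate in self.rates:
            if rate == 1:
                conv = nn.Conv2d(cin, cout, 1, bias=False, rng=rng)
            else:
                conv = nn.Conv2d(cin, cout, 3, pad=rate, dilation=rate,
                                 bias=False, rng=rng)
            self.branches.append(nn.Sequential(conv, nn.BatchNorm2d(cout),
                                               nn.ReLU()))
        self.gap_conv = nn.Conv2d(cin, cout, 1, rng=rng)
        self.project = nn.Sequential(
            nn.Conv2d(cout * (len(self.rates) + 1), cout, 1, bias=False,
                      rng=rng),
            nn.BatchNorm2d(cout), nn.ReLU())
        self.out_channels = cout

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        outs = [branch(x) for branch in self.branches]
        g = ops.relu(self.gap_conv(ops.global_avg_pool(x)))
        outs.append(ops.bilinear_resize(g, h, w))
        return self.project(ops.concat(outs, axis=1))


class DeeperLabC(nn.Module):
    """Full encoder-decoder; ``forward`` maps (N,1,S,S) to (N,2,S,S) logits."""

    def __init__(self, cfg: ModelConfig | None = None,
                 zero_init_residual: bool = False):
        super().__init__()
        self.cfg = cfg = cfg or ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg, rng, zero_init_residual)
        aspp_out = cfg.scaled(cfg.aspp_out_channels)
        self.aspp = ASPP(self.backbone.out_channels, aspp_out,
                         cfg.aspp_rates, rng)
        r = cfg.s2d_block
        self.ll_reduce = nn.Sequential(
            nn.Conv2d(self.backbone.lowlevel_channels,
                      cfg.lowlevel_reduced_channels, 1, bias=False, rng=rng),
            nn.BatchNorm2d(cfg.lowlevel_reduced_channels), nn.ReLU())
        fused_in = aspp_out + cfg.lowlevel_reduced_channels * r * r
        fuse_ch = cfg.scaled(cfg.fusion_channels)
        k, p = cfg.fusion_kernel, cfg.fusion_kernel // 2
        self.fusion = nn.Sequential(
            nn.Conv2d(fused_in, fuse_ch, k, pad=p, bias=False, rng=rng),
            nn.BatchNorm2d(fuse_ch), nn.ReLU(),
            nn.Conv2d(fuse_ch, fuse_ch, k, pad=p, bias=False, rng=rng),
            nn.BatchNorm2d(fuse_ch), nn.ReLU())
        self.head = nn.Conv2d(fuse_ch, cfg.num_classes * r * r, 1, rng=rng)
        self.fusion_channels_out = fuse_ch

    def forward(self, x: Tensor, return_features: bool = False):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        n, c, h, w = x.shape
        _check_side(h), _check_side(w)
        r = self.cfg.s2d_block
        low, high = self.backbone(x)
        ll = ops.space_to_depth(self.ll_reduce(low), r)
        hi = self.aspp(high)
        fused = self.fusion(ops.concat([hi, ll], axis=1))
        pred = ops.depth_to_space(self.head(fused), r)
        logits = ops.bilinear_resize(pred, h, w)
        if return_features:
            return logits, fused
        return logits


class ClassifierNet(nn.Module):
    """Backbone + global average pooling + linear 2-class head.

    The image-level classifier used to pre-train the backbone before
    segmentation training.
    """

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg, rng)
        # separate stream position for the head: keep backbone init
        # identical whether or not a head is attached
        head_rng = np.random.default_rng((cfg.seed, 1))
        self.fc = nn.Linear(self.backbone.out_channels, cfg.num_classes,
                            rng=head_rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        _, high = self.backbone(x)
        return self.fc(ops.flatten2d(ops.global_avg_pool(high)))


def predict_mask(logits: np.ndarray | Tensor) -> np.ndarray:
    """Per-pixel argmax over the 2 class channels; ties go to background.

    Accepts (2, H, W) or (N, 2, H, W); returns uint8 masks without the
    channel axis.
    """
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    if arr.shape[1] != 2:
        raise ValueError(f"expected 2 class channels, got {arr.shape[1]}")
    mask = (arr[:, 1] > arr[:, 0]).astype(np.uint8)
    return mask[0] if squeeze else mask


def save_checkpoint(path, model: nn.Module, cfg: ModelConfig,
                    seed: int | None = None, extra: dict | None = None) -> None:
    """Parameter archive (.npz) plus a JSON sidecar with config + seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta = {"config": cfg.to_dict(), "seed": seed}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path, kind: str = "segmenter"):
    """Rebuild a model from a checkpoint; returns (model, config, meta)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig.from_dict(meta["config"])
    model = DeeperLabC(cfg) if kind == "segmenter" else ClassifierNet(cfg)
    with np.load(path if path.suffix else path.with_suffix(".npz")) as state:
        model.load_state_dict(dict(state))
    model.eval()
    return model, cfg, meta
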