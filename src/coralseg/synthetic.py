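"""Synthetic single-channel coral scenes with paired masks and labels.

Positive scenes contain a union of randomly placed, rotated ellipses
("coral colonies") whose intensity is offset from the background and
carries a smooth sinusoidal texture; negatives are background only
(noise plus an optional vertical illumination gradient, mimicking the
low-light spectral frames the real system produces).  The pixel mask is
exactly the ellipse union and the image-level label is 1 iff the mask
contains at least one foreground pixel, matching the annotation scheme
of the real dataset (white coral on black background, image labels
1/0 for coral present/absent).

Generation is fully deterministic: sample ``i`` of a dataset is drawn
from ``np.random.default_rng([seed, i])``, so a dataset can be rebuilt
bit-identically from its JSON descriptor alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .preprocess import SampleRecord, save_gray_image, save_mask, write_manifest

__all__ = ["SceneConfig", "SyntheticSample", "generate_sample",
           "generate_arrays", "generate_dataset", "foreground_separability"]

# positive share of the emulated dataset: 2672 coral images out of 4131
DEFAULT_POSITIVE_FRACTION = 2672 / 4131


@dataclasses.dataclass
class SceneConfig:
    """Knobs of the scene generator.

    side: image side in pixels (desk-scale default 64; 512 is the
        full-scale canonical size).
    n_blobs: inclusive range for the number of ellipses per positive.
    blob_scale: ellipse semi-axis scale as a fraction of ``side``.
    blob_offset: intensity added inside coral relative to background.
    texture_amplitude: amplitude of the sinusoidal coral texture.
    background_level / background_noise_sd: Gaussian background model.
    illumination_gradient: multiply by a vertical ramp (0.6 -> 1.0).
    positive_fraction: probability a sample contains coral.
    """

    side: int = 64
    n_blobs: tuple[int, int] = (1, 4)
    blob_scale: float = 0.22
    blob_offset: float = 0.4
    texture_amplitude: float = 0.06
    background_level: float = 0.25
    background_noise_sd: float = 0.08
    illumination_gradient: bool = False
    positive_fraction: float = DEFAULT_POSITIVE_FRACTION
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.side < 16:
            raise ValueError("side must be >= 16")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "n_blobs" in d:
            d["n_blobs"] = tuple(d["n_blobs"])
        return cls(**d)


@dataclasses.dataclass
class SyntheticSample:
    image: np.ndarray       # float in [0, 1]
    mask: np.ndarray        # uint8 in {0, 1}
    image_label: int        # 1 iff mask has foreground
    noise_sd: float         # configured background noise, for contrast scores


def _ellipse_mask(side: int, cx: float, cy: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    x = xx - cx
    y = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u * u) / (a * a) + (v * v) / (b * b) <= 1.0


def draw_ellipse_params(cfg: SceneConfig, rng: np.random.Generator):
    """Ellipse parameter distribution (exposed so geometric oracles can
    sample it independently of the rasteriser)."""
    cx = rng.uniform(0.25, 0.75) * cfg.side
    cy = rng.uniform(0.25, 0.75) * cfg.side
    a = max(2.0, rng.uniform(0.4, 1.0) * cfg.blob_scale * cfg.side)
    b = max(2.0, rng.uniform(0.4, 1.0) * cfg.blob_scale * cfg.side)
    theta = rng.uniform(0.0, np.pi)
    return cx, cy, a, b, theta


def generate_sample(cfg: SceneConfig, rng: np.random.Generator) -> SyntheticSample:
    """Draw one scene.  Draw order (fixed for replayability): positive?,
    ellipse count, per-ellipse geometry, texture params, noise field."""
    side = cfg.side
    positive = rng.random() < cfg.positive_fraction
    mask = np.zeros((side, side), dtype=np.uint8)
    ellipses = []
    if positive:
        lo, hi = cfg.n_blobs
        n = int(rng.integers(lo, hi + 1))
        for _ in range(n):
            params = draw_ellipse_params(cfg, rng)
            ellipses.append(params)
            mask |= _ellipse_mask(side, *params).astype(np.uint8)
    # texture parameters are always drawn so the stream position does not
    # depend on the positive/negative branch beyond the ellipse draws
    fx = rng.uniform(2.0, 6.0) / side
    fy = rng.uniform(2.0, 6.0) / side
    phase = rng.uniform(0.0, 2 * np.pi)
    noise = rng.normal(0.0, cfg.background_noise_sd, (side, side))
    yy, xx = np.mgrid[0:side, 0:side]
    img = cfg.background_level + noise
    if positive:
        texture = cfg.texture_amplitude * np.sin(
            2 * np.pi * (fx * xx + fy * yy) + phase)
        img = img + mask * (cfg.blob_offset + texture)
    if cfg.illumination_gradient:
        ramp = 0.6 + 0.4 * (yy / max(side - 1, 1))
        img = img * ramp
    img = np.clip(img, 0.0, 1.0)
    label = int(mask.any())
    if positive and label == 0:  # cannot happen with >=2 px semi-axes
        raise RuntimeError("positive sample rasterised to an empty mask")
    return SyntheticSample(image=img, mask=mask, image_label=label,
                           noise_sd=cfg.background_noise_sd)


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def generate_arrays(cfg: SceneConfig, n: int):
    """n samples as stacked arrays: (images, masks, labels)."""
    samples = [generate_sample(cfg, _sample_rng(cfg.seed, i)) for i in range(n)]
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples])
    labels = np.array([s.image_label for s in samples], dtype=np.int64)
    return images, masks, labels


def generate_dataset(cfg: SceneConfig, n: int, outdir, *,
                     split_fraction: float = 0.9) -> Path:
    """Write n samples (grayscale PNGs + masks), a train/val manifest and
    a JSON descriptor of ``cfg``; returns the manifest path.

    The split shuffles deterministically by seed and assigns
    ``round(n * split_fraction)`` samples to training.
    """
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(n - 1)))
    n_train = int(round(n * split_fraction))
    order = np.random.default_rng([cfg.seed, n, 0xC0]).permutation(n)
    split_of = {int(idx): ("train" if rank < n_train else "val")
                for rank, idx in enumerate(order)}
    records = []
    for i in range(n):
        sample = generate_sample(cfg, _sample_rng(cfg.seed, i))
        img_rel = f"images/img_{i:0{width}d}.png"
        mask_rel = f"masks/mask_{i:0{width}d}.png"
        save_gray_image(outdir / img_rel, sample.image)
        save_mask(outdir / mask_rel, sample.mask)
        records.append(SampleRecord(image_path=img_rel, mask_path=mask_rel,
                                    image_label=sample.image_label,
                                    split=split_of[i]))
    manifest = outdir / "manifest.csv"
    write_manifest(manifest, records)
    descriptor = {"scene_config": cfg.to_dict(), "n": n,
                  "split_fraction": split_fraction}
    (outdir / "dataset.json").write_text(json.dumps(descriptor, indent=2))
    return manifest


def foreground_separability(sample: SyntheticSample) -> float:
    """Contrast score |mean(inside) - mean(outside)| / background noise sd.

    With zero configured noise the raw intensity contrast is returned
    (denominator 1), so a noiseless, textureless scene scores exactly
    the blob intensity offset.
    """
    mask = sample.mask.astype(bool)
    if not mask.any():
        raise ValueError("separability is defined for positive samples only")
    inside = float(sample.image[mask].mean())
    outside = float(sample.image[~mask].mean())
    denom = sample.noise_sd if sample.noise_sd > 0 else 1.0
    return abs(inside - outside) / denom
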