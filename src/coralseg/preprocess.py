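"""Image/mask I/O, canonicalisation to single-channel squares, and paired
training-time augmentation.

All imagery flows through the package as float arrays in [0, 1] (images)
or uint8 arrays in {0, 1} (masks), row-major with the origin at the
top-left pixel.  On disk both are 8-bit grayscale PNG (JPEG/TIFF are
accepted on read).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import transform as sktransform

__all__ = [
    "ChannelCountError", "SampleRecord",
    "load_gray_image", "save_gray_image", "split_rgb_channels",
    "pad_to_square", "resize_to_canonical", "binarize_mask", "load_mask",
    "save_mask", "canonicalize", "augment_pair",
    "read_manifest", "write_manifest",
]

CANONICAL_SIDE = 512


class ChannelCountError(ValueError):
    """Raised when an image has the wrong number of channels."""


@dataclasses.dataclass
class SampleRecord:
    """One dataset row: an image, its optional pixel mask, and the
    image-level coral-present label."""

    image_path: str
    mask_path: str | None
    image_label: int
    split: str = "train"
    source_kind: str = "rgb_channel"


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def load_gray_image(path) -> np.ndarray:
    """Read a single-channel raster, scaled to [0, 1].

    Colour inputs are rejected: split them with
    :func:`split_rgb_channels` first.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ChannelCountError(
                f"{path}: expected 1 channel, found {arr.shape[2]}; "
                "split colour images into channels first")
    return _to_unit_float(arr)


def save_gray_image(path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.asarray(img, dtype=np.float64), 0, 1)
    iio.imwrite(path, np.round(data * 255).astype(np.uint8))


def split_rgb_channels(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an (H, W, 3) raster into three [0, 1] single-channel images
    in R, G, B order."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ChannelCountError(
            f"expected an (H, W, 3) raster, got shape {rgb.shape}")
    r, g, b = (_to_unit_float(rgb[:, :, i]) for i in range(3))
    return r, g, b


def pad_to_square(img: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Centre the image on a square canvas of side max(H, W), padding the
    short axis with black (value 0).  Square inputs pass through."""
    img = np.asarray(img)
    h, w = img.shape
    side = max(h, w)
    if h == w:
        return img
    top = (side - h) // 2
    left = (side - w) // 2
    out = np.full((side, side), fill, dtype=img.dtype)
    out[top:top + h, left:left + w] = img
    return out


def _nearest_index(n_in: int, n_out: int) -> np.ndarray:
    # half-pixel-centre source coordinates, floored
    return np.minimum(
        np.floor((np.arange(n_out) + 0.5) * n_in / n_out).astype(int),
        n_in - 1)


def resize_to_canonical(img: np.ndarray, side: int = CANONICAL_SIDE, *,
                        is_mask: bool = False) -> np.ndarray:
    """Scale a square image to side x side.

    Intensity images use bilinear interpolation; masks use
    nearest-neighbour so they stay binary.
    """
    img = np.asarray(img)
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"resize expects a square input, got {img.shape}; "
                         "pad_to_square first")
    if side < 1:
        raise ValueError("side must be >= 1")
    if img.shape[0] == side:
        return img
    if is_mask:
        idx = _nearest_index(img.shape[0], side)
        return img[np.ix_(idx, idx)]
    return sktransform.resize(img.astype(np.float64), (side, side), order=1,
                              mode="edge", anti_aliasing=img.shape[0] > side)


def binarize_mask(img: np.ndarray) -> np.ndarray:
    """Threshold a grayscale annotation at 0.5: white (coral) -> 1,
    black (background) -> 0."""
    return (np.asarray(img) > 0.5).astype(np.uint8)


def load_mask(path) -> np.ndarray:
    return binarize_mask(load_gray_image(path))


def save_mask(path, mask: np.ndarray) -> None:
    save_gray_image(path, np.asarray(mask, dtype=np.float64))


def canonicalize(img: np.ndarray, side: int = CANONICAL_SIDE, *,
                 is_mask: bool = False) -> np.ndarray:
    """pad_to_square then resize_to_canonical."""
    return resize_to_canonical(pad_to_square(img), side, is_mask=is_mask)


def augment_pair(img: np.ndarray, mask: np.ndarray | None,
                 rng: np.random.Generator, *, return_params: bool = False):
    """Random paired augmentation: each of rotation (angle uniform on
    [0, 180] degrees, counter-clockwise about the centre, zero fill),
    horizontal flip and vertical flip fires independently with
    probability 0.5.

    The draw order is fixed — rotate?, angle (only when rotation fires),
    hflip?, vflip? — so a seeded run is replayable.  The identical
    geometric transform is applied to image and mask; the mask is
    resampled nearest-neighbour and stays binary.
    """
    img = np.asarray(img, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != img.shape:
            raise ValueError(
                f"image/mask shape mismatch: {img.shape} vs {mask.shape}")
    do_rot = rng.random() < 0.5
    angle = float(rng.uniform(0.0, 180.0)) if do_rot else 0.0
    do_h = rng.random() < 0.5
    do_v = rng.random() < 0.5
    if do_rot:
        img = sktransform.rotate(img, angle, order=1, cval=0.0,
                                 preserve_range=True)
        if mask is not None:
            mask = sktransform.rotate(mask.astype(np.float64), angle, order=0,
                                      cval=0.0, preserve_range=True)
            mask = mask.astype(np.uint8)
    if do_h:
        img = img[:, ::-1].copy()
        if mask is not None:
            mask = mask[:, ::-1].copy()
    if do_v:
        img = img[::-1, :].copy()
        if mask is not None:
            mask = mask[::-1, :].copy()
    result = (img, mask)
    if return_params:
        return result + ({"rotate": do_rot, "angle": angle,
                          "hflip": do_h, "vflip": do_v},)
    return result


# ---------------------------------------------------------------------------
# dataset manifests
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["image_path", "mask_path", "image_label", "split"]


def write_manifest(path, records: list[SampleRecord]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([{
        "image_path": r.image_path,
        "mask_path": r.mask_path if r.mask_path else "",
        "image_label": int(r.image_label),
        "split": r.split,
    } for r in records], columns=_MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_manifest(path) -> list[SampleRecord]:
    """Read a dataset manifest; relative file paths are resolved against
    the manifest's own directory."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"image_path": str, "mask_path": str})
    base = path.parent

    def _resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    records = []
    for row in df.itertuples(index=False):
        mask = row.mask_path if isinstance(row.mask_path, str) and row.mask_path else None
        records.append(SampleRecord(image_path=_resolve(row.image_path),
                                    mask_path=_resolve(mask) if mask else None,
                                    image_label=int(row.image_label),
                                    split=str(row.split)))
    return records
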