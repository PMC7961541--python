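"""Class-activation mapping: turning the two class response maps of the
weakly supervised head into a per-pixel coral-evidence heat map.

The head produces a non-coral map N0 and a coral map N1 of equal size.
Global average pooling reduces each to its mean G_j = (1/(h*w)) * sum N_j;
the scalar class weights (w0, w1) turn those means into image-level
class scores, and the same weights combine the maps themselves into the
raw activation map CAM = w0*N0 + w1*N1.  Min-max normalisation rescales
the raw map to [0, 100] % so it reads as a per-pixel coral probability.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cam_head_forward", "activation_mean", "compute_cam",
           "normalize_cam", "render_heatmap"]


def cam_head_forward(features: np.ndarray, conv_weight: np.ndarray,
                     linear_weight: np.ndarray, class_bias: np.ndarray):
    """Apply the 1x1 CAM head to (n, C, h, w) features.

    Returns (N0, N1, scores): the two response maps, each (n, h, w), and
    the image-level class scores (n, 2) formed by the (2, 2) linear map
    of the pooled means (G0, G1).  The coral row of ``linear_weight``
    holds the scalar weights (w0, w1) that also combine the maps into
    the activation map.
    """
    features = np.asarray(features)
    maps = np.einsum("ocij,nchw->nohw", conv_weight, features)
    g = maps.mean(axis=(2, 3))
    scores = g @ np.asarray(linear_weight).T + np.asarray(class_bias)
    return maps[:, 0], maps[:, 1], scores


def activation_mean(n_map: np.ndarray) -> float:
    """Global average pool of one response map: G = (1/(h*w)) * sum N."""
    return float(np.asarray(n_map, dtype=np.float64).mean())


def compute_cam(n0: np.ndarray, n1: np.ndarray, w0: float,
                w1: float) -> np.ndarray:
    """Raw activation map: elementwise w0*N0 + w1*N1."""
    n0 = np.asarray(n0, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    if n0.shape != n1.shape:
        raise ValueError(f"map shapes differ: {n0.shape} vs {n1.shape}")
    return w0 * n0 + w1 * n1


def normalize_cam(raw: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 100] %: (raw - min) / (max - min) * 100.

    Works on one map (H, W) or a batch (N, H, W); each map is normalised
    independently.  A constant map (max == min) maps to all zeros.
    """
    raw = np.asarray(raw, dtype=np.float64)
    single = raw.ndim <= 1 or raw.ndim == 2
    batch = raw[None] if single else raw
    flat = batch.reshape(len(batch), -1)
    lo = flat.min(axis=1)
    hi = flat.max(axis=1)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = (batch - lo.reshape(-1, *[1] * (batch.ndim - 1))) \
        / safe.reshape(-1, *[1] * (batch.ndim - 1)) * 100.0
    out[span == 0] = 0.0
    return out[0] if single else out


def render_heatmap(cam: np.ndarray, base: np.ndarray,
                   alpha: float = 0.5) -> np.ndarray:
    """Composite a normalised [0, 100] activation map over a grayscale
    base image with a blue-to-red colormap; returns uint8 RGB.

    High values render red (likely coral), low values blue.
    """
    from matplotlib import colormaps
    from skimage import transform as sktransform

    cam = np.asarray(cam, dtype=np.float64)
    base = np.asarray(base, dtype=np.float64)
    if cam.shape != base.shape:
        cam = sktransform.resize(cam, base.shape, order=1, mode="edge",
                                 anti_aliasing=False)
    colors = colormaps["jet"](np.clip(cam, 0, 100) / 100.0)[..., :3]
    gray = np.repeat(base[..., None], 3, axis=2)
    out = (1 - alpha) * gray + alpha * colors
    return np.round(np.clip(out, 0, 1) * 255).astype(np.uint8)
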