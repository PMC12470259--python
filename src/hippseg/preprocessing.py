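"""Slice conditioning: normalization, pad/crop round-trip, CLAHE, Gaussian
denoising, and paired flip augmentation.

Images are 2D float arrays in [0, 1]; masks are exact {0, 1} arrays.  Masks
only ever pass through the geometric operations (pad, crop, flip) — never
through intensity transforms — and every geometric transform is applied with
identical parameters to an image and its mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import exposure

from .errors import ConfigurationError, ValidationError

_CLAHE_NBINS = 256


@dataclass(frozen=True)
class PadSpec:
    """Placement metadata recorded by :func:`pad_to_canvas` so that
    :func:`crop_back` is an exact inverse."""

    original_size: tuple[int, int]
    offset: tuple[int, int]
    target: tuple[int, int]


def normalize_intensity(raw: np.ndarray) -> np.ndarray:
    """Per-slice min-max scaling to [0, 1]; a constant slice maps to zeros."""
    raw = np.asarray(raw, dtype=np.float64)
    if not np.isfinite(raw).all():
        raise ValidationError("slice contains non-finite values")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def pad_to_canvas(img: np.ndarray, target: tuple[int, int] = (256, 256)
                  ) -> tuple[np.ndarray, PadSpec]:
    """Zero-pad a slice onto a centred canvas of ``target`` size.

    Returns the padded array and a :class:`PadSpec`; feeding both to
    :func:`crop_back` reproduces the input exactly.  Inputs larger than the
    canvas are rejected rather than silently downscaled.
    """
    img = np.asarray(img)
    h, w = img.shape
    th, tw = target
    if h > th or w > tw:
        raise ValidationError(
            f"slice of size {h}x{w} does not fit on a {th}x{tw} canvas")
    top = (th - h) // 2
    left = (tw - w) // 2
    out = np.zeros((th, tw), dtype=img.dtype)
    out[top:top + h, left:left + w] = img
    return out, PadSpec(original_size=(h, w), offset=(top, left), target=(th, tw))


def crop_back(img: np.ndarray, spec: PadSpec) -> np.ndarray:
    """Exact inverse of :func:`pad_to_canvas`."""
    img = np.asarray(img)
    if img.shape != spec.target:
        raise ValidationError(
            f"padded shape {img.shape} does not match recorded canvas {spec.target}")
    top, left = spec.offset
    h, w = spec.original_size
    return img[top:top + h, left:left + w].copy()


def clahe(img: np.ndarray, clip_limit: float = 2.0,
          tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] slice.

    ``clip_limit`` uses the conventional OpenCV scale (histogram clip as a
    multiple of the uniform bin height; default 2.0) and is converted to the
    normalized clip fraction scikit-image expects.  Applied to images only,
    never to masks.
    """
    if clip_limit <= 0:
        raise ConfigurationError("clip_limit must be positive")
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        raise ValidationError("clahe expects intensities in [0, 1]")
    h, w = img.shape
    kernel = (max(1, h // tiles[0]), max(1, w // tiles[1]))
    out = exposure.equalize_adapthist(
        img, kernel_size=kernel, clip_limit=clip_limit / _CLAHE_NBINS,
        nbins=_CLAHE_NBINS)
    return np.clip(out, 0.0, 1.0)


def gaussian_denoise(img: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Linear Gaussian smoothing; ``mode='nearest'`` keeps the slice mean
    stable up to boundary effects."""
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    return gaussian_filter(np.asarray(img, dtype=np.float64), sigma=sigma,
                           mode="nearest")


def augment_pair(img: np.ndarray, mask: np.ndarray, rng_seed: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Random horizontal/vertical flips (each with probability 0.5), applied
    identically to a slice and its mask; fully determined by ``rng_seed``."""
    img = np.asarray(img)
    mask = np.asarray(mask)
    if img.shape != mask.shape:
        raise ValidationError(
            f"image shape {img.shape} != mask shape {mask.shape}")
    rng = np.random.default_rng(rng_seed)
    if rng.random() < 0.5:   # horizontal flip: left-right
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < 0.5:   # vertical flip: up-down
        img, mask = img[::-1, :], mask[::-1, :]
    return img.copy(), mask.copy()
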