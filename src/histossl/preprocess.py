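"""Patch preprocessing: background rejection, resize, normalisation, augmentation.

Patches are 8-bit RGB arrays (H, W, 3).  The background filter operationalises
"no cell tissue" as a white-fraction rule: a pixel is glass when its darkest
channel exceeds ``background_white_threshold``, and a patch is background when
the glass fraction exceeds ``background_fraction_max``.  Resizing uses
bilinear interpolation with corner-aligned sampling: output pixel i samples
source coordinate i * (src - 1) / (dst - 1), so the image corners map onto
each other exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class PreprocessConfig:
    background_white_threshold: int = 220
    background_fraction_max: float = 0.8
    target_size: int = 32
    augmentations: dict = field(default_factory=lambda: {
        "zoom": True, "flip": True, "color": True})
    # mild ranges: augmentation should emulate plausible acquisition
    # variation without drowning class-level colour statistics
    zoom_range: tuple[float, float] = (1.0, 1.15)
    color_jitter_range: tuple[float, float] = (0.98, 1.02)

    def __post_init__(self) -> None:
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")
        if self.zoom_range[0] > self.zoom_range[1]:
            raise ValueError("zoom_range lo must be <= hi")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) image, got {img.shape}")
    return img


def is_background(img: np.ndarray, config: PreprocessConfig | None = None) -> bool:
    """True when the white-glass pixel fraction exceeds the configured cap."""
    config = config or PreprocessConfig()
    img = _check_rgb(img)
    white = img.min(axis=2) > config.background_white_threshold
    return bool(white.mean() > config.background_fraction_max)


def normalize(img: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to [-1, 1] per channel: x/127.5 - 1."""
    return np.asarray(img, dtype=np.float64) / 127.5 - 1.0


def denormalize(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint((np.asarray(arr) + 1.0) * 127.5), 0, 255).astype(np.uint8)


def resize_bilinear(img: np.ndarray, target_size: int) -> np.ndarray:
    """Bilinear resize to target_size x target_size, corner-aligned.

    Output dtype matches the input (rounded for integer inputs).
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    img = np.asarray(img)
    h, w = img.shape[:2]
    if h < 2 or w < 2:
        raise ValueError("source image must be at least 2x2")
    rows = np.linspace(0.0, h - 1.0, target_size)
    cols = np.linspace(0.0, w - 1.0, target_size)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])
    if img.ndim == 2:
        out = map_coordinates(img.astype(np.float64), coords, order=1,
                              mode="nearest").reshape(target_size, target_size)
    else:
        planes = [map_coordinates(img[..., c].astype(np.float64), coords,
                                  order=1, mode="nearest")
                  .reshape(target_size, target_size)
                  for c in range(img.shape[2])]
        out = np.stack(planes, axis=-1)
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(img.dtype)
    return out.astype(img.dtype)


def augment(img: np.ndarray, config: PreprocessConfig, seed: int) -> np.ndarray:
    """Random flip / central zoom / per-channel colour scaling, seeded.

    With every augmentation flag off this is the identity.
    """
    img = _check_rgb(img)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    out = img
    if config.augmentations.get("flip", False):
        if rng.random() < 0.5:
            out = out[:, ::-1]
        if rng.random() < 0.5:
            out = out[::-1, :]
    if config.augmentations.get("zoom", False):
        factor = rng.uniform(*config.zoom_range)
        if factor > 1.0:
            h, w = out.shape[:2]
            ch, cw = max(2, int(round(h / factor))), max(2, int(round(w / factor)))
            r0, c0 = (h - ch) // 2, (w - cw) // 2
            crop = out[r0:r0 + ch, c0:c0 + cw]
            # re-crop to original size via square bilinear resize per side
            out = _resize_rect(crop, h, w)
    if config.augmentations.get("color", False):
        scales = rng.uniform(*config.color_jitter_range, size=3)
        out = np.clip(np.rint(out.astype(np.float64) * scales), 0, 255
                      ).astype(np.uint8)
    return np.ascontiguousarray(out)


def _resize_rect(img: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    h, w = img.shape[:2]
    rows = np.linspace(0.0, h - 1.0, target_h)
    cols = np.linspace(0.0, w - 1.0, target_w)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])
    planes = [map_coordinates(img[..., c].astype(np.float64), coords, order=1,
                              mode="nearest").reshape(target_h, target_w)
              for c in range(img.shape[2])]
    out = np.stack(planes, axis=-1)
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(img.dtype)
    return out.astype(img.dtype)


def downsample_area(img: np.ndarray, target_size: int) -> np.ndarray:
    """Anti-aliased downsample to target_size x target_size (area averaging).

    Used for the large reduction from the 300-px labelling resolution to the
    backbone's working resolution, where plain bilinear point-sampling would
    alias away texture statistics;  :func:`resize_bilinear` remains the right
    tool for small backbone-side adjustments (e.g. 300 -> 299).
    """
    from skimage.transform import resize

    img = _check_rgb(img)
    out = resize(img.astype(np.float64), (target_size, target_size),
                 anti_aliasing=True, preserve_range=True)
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(img.dtype)
    return out.astype(img.dtype)


def prepare_features(img: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Downsample to the working resolution and normalise to [-1, 1]."""
    return normalize(downsample_area(_check_rgb(img), config.target_size))
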