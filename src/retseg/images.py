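"""Image and mask file IO.

Images load as float arrays in [0, 1], channel-first (3, H, W); masks load
as strict {0, 1} uint8 rasters, binarised at half of the source bit depth
with a warning when the file holds more than two intensity levels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger("retseg")

__all__ = ["load_image", "load_mask", "save_image", "save_mask"]


def _full_scale(arr: np.ndarray) -> float:
    if arr.dtype == np.uint8:
        return 255.0
    if arr.dtype == np.uint16:
        return 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return 1.0
    raise ValueError(f"unsupported image dtype {arr.dtype}")


def load_image(path) -> np.ndarray:
    """Read an RGB image file into a (3, H, W) float array in [0, 1]."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable / non-image file
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    scale = _full_scale(arr)
    arr = arr.astype(np.float64) / scale
    if arr.ndim == 2:  # grayscale -> replicate
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected RGB image, got shape {arr.shape}")
    return np.clip(arr, 0.0, 1.0).transpose(2, 0, 1)


def load_mask(path) -> np.ndarray:
    """Read a single-channel mask into a strict {0,1} uint8 (H, W) raster."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read mask file {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    scale = _full_scale(arr)
    levels = np.unique(arr)
    if len(levels) > 2:
        logger.warning(
            "mask %s has %d intensity levels; binarising at half scale",
            path,
            len(levels),
        )
    return (arr.astype(np.float64) / scale > 0.5).astype(np.uint8)


def save_image(path, img: np.ndarray) -> None:
    """Write a (3, H, W) float [0,1] array as an 8-bit RGB PNG."""
    arr = np.clip(np.asarray(img), 0.0, 1.0)
    out = np.round(arr.transpose(1, 2, 0) * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), out)


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary (H, W) mask as an 8-bit single-channel PNG."""
    out = (np.asarray(mask) > 0).astype(np.uint8) * 255
    iio.imwrite(Path(path), out)
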