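"""Fundus photograph preprocessing.

Raw retinal photographs arrive at arbitrary resolutions with black borders
around the circular field of view.  The pipeline (1) crops the tight
bounding box of non-blank pixels, (2) applies per-channel global histogram
equalisation restricted to the retinal field, (3) rescales with bicubic
interpolation so the longer side matches the target size, padding
symmetrically to a square (aspect ratio preserved, never stretched), and
(4) min-max normalises intensities to [0, 1].  Masks ride through the same
crop and resize with nearest-neighbour interpolation and re-binarisation so
image/mask alignment is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

__all__ = [
    "PreprocessConfig",
    "crop_blank_borders",
    "equalize_histogram",
    "resize_to_target",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    crop_threshold: float = 0.02
    target_size: int = 512
    equalize: bool = True
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.target_size < 32:
            raise ValueError("target_size must be at least 32")
        if not 0.0 <= self.crop_threshold < 1.0:
            raise ValueError("crop_threshold must lie in [0, 1)")


def field_of_view(img: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean (H, W) mask of pixels whose max-channel intensity exceeds threshold."""
    return np.asarray(img).max(axis=0) > threshold


def crop_blank_borders(
    img: np.ndarray, threshold: float = 0.02
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Crop the tight bounding box of non-blank pixels.

    Returns the cropped image and the crop box ``(row0, row1, col0, col1)``
    (half-open), which callers apply identically to masks.
    """
    fov = field_of_view(img, threshold)
    if not fov.any():
        raise ValueError("image is entirely blank at the given threshold")
    rows = np.flatnonzero(fov.any(axis=1))
    cols = np.flatnonzero(fov.any(axis=0))
    box = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    return img[:, box[0] : box[1], box[2] : box[3]], box


def crop_mask(mask: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    return mask[box[0] : box[1], box[2] : box[3]]


def equalize_histogram(img: np.ndarray, fov: np.ndarray | None = None) -> np.ndarray:
    """Per-channel global histogram equalisation inside the retinal field.

    Pixels outside ``fov`` (the blank surround) keep their original values so
    the background does not skew the histogram, and stays black.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("intensities must lie in [0, 1]")
    out = np.empty_like(img)
    for c in range(img.shape[0]):
        eq = exposure.equalize_hist(img[c], mask=fov)
        out[c] = np.where(fov, eq, img[c]) if fov is not None else eq
    return np.clip(out, 0.0, 1.0)


def _resize_geometry(h: int, w: int, target: int) -> tuple[int, int, int, int]:
    """Scaled size plus top/left pad for aspect-preserving fit into target²."""
    scale = target / max(h, w)
    nh = max(1, int(round(h * scale)))
    nw = max(1, int(round(w * scale)))
    nh, nw = min(nh, target), min(nw, target)
    return nh, nw, (target - nh) // 2, (target - nw) // 2


def resize_to_target(
    img: np.ndarray,
    masks: dict[str, np.ndarray] | None,
    cfg: PreprocessConfig,
) -> tuple[np.ndarray, dict[str, np.ndarray] | None]:
    """Bicubic rescale of the longer side to ``target_size``, then symmetric
    padding with ``pad_value`` to a square; masks use nearest-neighbour and
    are re-binarised."""
    img = np.asarray(img, dtype=np.float64)
    _, h, w = img.shape
    t = cfg.target_size
    nh, nw, top, left = _resize_geometry(h, w, t)
    scaled = transform.resize(
        img, (img.shape[0], nh, nw), order=3, anti_aliasing=(nh < h or nw < w)
    )
    out = np.full((img.shape[0], t, t), cfg.pad_value, dtype=np.float64)
    out[:, top : top + nh, left : left + nw] = np.clip(scaled, 0.0, 1.0)
    out_masks = None
    if masks is not None:
        out_masks = {}
        for name, m in masks.items():
            ms = transform.resize(
                m.astype(np.float64), (nh, nw), order=0, anti_aliasing=False
            )
            mm = np.zeros((t, t), dtype=np.uint8)
            mm[top : top + nh, left : left + nw] = (ms > 0.5).astype(np.uint8)
            out_masks[name] = mm
    return out, out_masks


def preprocess(
    img: np.ndarray,
    masks: dict[str, np.ndarray] | None = None,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> tuple[np.ndarray, dict[str, np.ndarray] | None]:
    """Full pipeline: crop -> equalise -> resize -> min-max normalise.

    Masks receive the crop and resize only (geometric transforms), never the
    intensity transforms.
    """
    cropped, box = crop_blank_borders(img, cfg.crop_threshold)
    cmasks = None
    if masks is not None:
        cmasks = {name: crop_mask(m, box) for name, m in masks.items()}
    if cfg.equalize:
        fov = field_of_view(cropped, cfg.crop_threshold)
        cropped = equalize_histogram(cropped, fov)
    out, out_masks = resize_to_target(cropped, cmasks, cfg)
    lo, hi = out.min(), out.max()
    if hi > lo:
        out = (out - lo) / (hi - lo)
    return out, out_masks
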