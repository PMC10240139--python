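"""Synthetic retina-like images with exact per-lesion ground truth.

Each sample is a circular orange-brown retinal field on a black background
with curved dark vessel strokes and a bright optic-disc ellipse, into which
four lesion families are painted:

* **MA** (microaneurysms) — small dark-red discs, radius 1-3 px, the
  smallest and hardest class;
* **HE** (hemorrhages) — irregular dark-red blot-shaped blobs;
* **EX** (hard exudates) — vivid yellow-white patches, the most prevalent;
* **SE** (soft exudates) — pale, low-contrast greyish blobs.

The exact painted support of each family is returned as its binary mask
(additive Gaussian pixel noise is applied afterwards, so masks stay exact).
Lesions are placed without mutual overlap, entirely inside the field of
view.  Everything is driven by a single seed, so a fixed configuration
reproduces a bit-identical dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .images import save_image, save_mask
from .manifest import DatasetManifest, ManifestEntry
from .network import LESIONS

logger = logging.getLogger("retseg")

__all__ = ["SyntheticConfig", "generate_sample", "generate_arrays", "generate_dataset"]


def _default_lesion_params() -> dict[str, dict[str, tuple[int, int]]]:
    # count and radius ranges (inclusive), tuned so expected pixel
    # prevalence orders EX > HE > SE > MA, mirroring real lesion burden
    return {
        "EX": {"count": (6, 12), "radius": (3, 7)},
        "HE": {"count": (3, 6), "radius": (4, 8)},
        "SE": {"count": (1, 3), "radius": (4, 9)},
        "MA": {"count": (3, 8), "radius": (1, 3)},
    }


@dataclass
class SyntheticConfig:
    """Generator settings; defaults describe the desk-scale study conditions."""

    image_size: int = 128
    n_labeled: int = 40
    n_unlabeled: int = 200
    lesion_params: dict = field(default_factory=_default_lesion_params)
    vessel_count: int = 6
    noise_sd: float = 0.02
    contrast: float = 0.9  # lesion-vs-background blend strength in (0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labeled < 0 or self.n_unlabeled < 0:
            raise ValueError("sample counts must be non-negative")
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must lie in (0, 1]")
        for name, p in self.lesion_params.items():
            if p["radius"][0] <= 0 or p["count"][0] < 0:
                raise ValueError(f"invalid ranges for lesion {name}")


# lesion paint colours (R, G, B); SE is deliberately close to the fundus tone
_COLORS = {
    "MA": (0.36, 0.08, 0.05),
    "HE": (0.30, 0.06, 0.05),
    "EX": (0.98, 0.95, 0.55),
    "SE": (0.86, 0.80, 0.72),
}
_FIELD = (0.72, 0.35, 0.12)
_VESSEL = (0.38, 0.13, 0.06)
_DISC = (0.95, 0.85, 0.55)


def _blob_support(
    yy: np.ndarray,
    xx: np.ndarray,
    cy: float,
    cx: float,
    r: float,
    rng: np.random.Generator,
    irregularity: float,
) -> np.ndarray:
    """Star-convex blob: radius modulated by random low-order harmonics."""
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    if irregularity == 0:
        return dist <= r
    theta = np.arctan2(dy, dx)
    mod = np.ones_like(theta)
    for k in (2, 3, 5):
        mod += irregularity * rng.uniform(-1, 1) / k * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return dist <= r * np.clip(mod, 0.4, 1.4)


def _draw_vessels(
    img: np.ndarray, field_mask: np.ndarray, disc_c, n_vessels: int, rng
) -> None:
    h = img.shape[1]
    yy, xx = np.mgrid[0:h, 0:h]
    for _ in range(n_vessels):
        # quadratic bezier from the optic disc to a random rim point
        ang = rng.uniform(0, 2 * np.pi)
        end = (
            h / 2 + 0.44 * h * np.sin(ang),
            h / 2 + 0.44 * h * np.cos(ang),
        )
        ctrl = (
            (disc_c[0] + end[0]) / 2 + rng.uniform(-0.15, 0.15) * h,
            (disc_c[1] + end[1]) / 2 + rng.uniform(-0.15, 0.15) * h,
        )
        t = np.linspace(0, 1, 4 * h)[:, None]
        pts = (
            (1 - t) ** 2 * np.array(disc_c) + 2 * (1 - t) * t * np.array(ctrl) + t**2 * np.array(end)
        )
        thickness = rng.uniform(0.8, 1.8)
        centreline = np.ones((h, h), dtype=bool)
        px = np.clip(np.round(pts).astype(int), 0, h - 1)
        centreline[px[:, 0], px[:, 1]] = False
        stroke = ndimage.distance_transform_edt(centreline) <= thickness
        stroke &= field_mask
        alpha = 0.85
        for c in range(3):
            img[c][stroke] = (1 - alpha) * img[c][stroke] + alpha * _VESSEL[c]


def generate_sample(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render one labelled sample: an RGB image and the four lesion masks."""
    h = cfg.image_size
    yy, xx = np.mgrid[0:h, 0:h]
    cy = cx = (h - 1) / 2.0
    field_r = 0.47 * h
    dist = np.hypot(yy - cy, xx - cx)
    field_mask = dist <= field_r

    # fundus base: radially shaded orange-brown with mild per-sample jitter
    shade = 1.0 - 0.35 * (dist / field_r) ** 2
    jitter = 1.0 + rng.uniform(-0.06, 0.06, size=3)
    img = np.zeros((3, h, h))
    for c in range(3):
        img[c] = np.where(field_mask, _FIELD[c] * jitter[c] * shade, 0.0)

    # optic disc: bright ellipse off-centre
    disc_c = (cy + rng.uniform(-0.08, 0.08) * h, cx + 0.28 * h)
    da, db = 0.07 * h, 0.055 * h
    disc = ((yy - disc_c[0]) / da) ** 2 + ((xx - disc_c[1]) / db) ** 2 <= 1
    disc &= field_mask
    for c in range(3):
        img[c][disc] = 0.3 * img[c][disc] + 0.7 * _DISC[c]

    _draw_vessels(img, field_mask, disc_c, cfg.vessel_count, rng)

    scale = cfg.image_size / 128.0
    occupancy = np.zeros((h, h), dtype=bool)
    masks: dict[str, np.ndarray] = {}
    irregularity = {"MA": 0.0, "HE": 0.6, "EX": 0.5, "SE": 0.3}
    for name in ("EX", "HE", "SE", "MA"):  # big families first eases placement
        params = cfg.lesion_params[name]
        n_target = int(rng.integers(params["count"][0], params["count"][1] + 1))
        lesion_mask = np.zeros((h, h), dtype=bool)
        placed = 0
        attempts = 0
        while placed < n_target and attempts < 60 * max(1, n_target):
            attempts += 1
            r = rng.uniform(*params["radius"]) * (scale if name != "MA" else 1.0)
            r = max(1.0, r)
            if field_r - r - 3 <= 0:
                break  # lesion cannot fit in this field at all
            # position uniform over the usable disc area
            rad = (field_r - r - 3) * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            py, px = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            # work on a local window: blob radius is at most 1.4 r
            margin = int(np.ceil(1.4 * r + 3))
            y0, y1 = max(0, int(py) - margin), min(h, int(py) + margin + 1)
            x0, x1 = max(0, int(px) - margin), min(h, int(px) + margin + 1)
            win = np.s_[y0:y1, x0:x1]
            wyy, wxx = yy[win], xx[win]
            clearance = np.hypot(wyy - py, wxx - px) <= 1.4 * r + 2
            if (occupancy[win] & clearance).any() or (disc[win] & clearance).any():
                continue
            support = _blob_support(wyy, wxx, py, px, r, rng, irregularity[name])
            support &= field_mask[win]
            if not support.any():
                continue
            alpha = cfg.contrast * (0.55 if name == "SE" else 1.0)
            for c in range(3):
                img[c][win][support] = (
                    (1 - alpha) * img[c][win][support] + alpha * _COLORS[name][c]
                )
            lesion_mask[win] |= support
            occupancy[win] |= clearance
            placed += 1
        if placed < n_target:
            logger.info(
                "sample rendered with %d/%d %s lesions (placement exhausted)",
                placed,
                n_target,
                name,
            )
        masks[name] = lesion_mask.astype(np.uint8)

    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    # re-order masks to the canonical lesion order
    return img, {name: masks[name] for name in LESIONS}


def generate_unlabeled_sample(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    img, _ = generate_sample(cfg, rng)
    return img


def _sample_rng(seed: int, kind: str, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, 0 if kind == "labeled" else 1, index])


def generate_arrays(
    cfg: SyntheticConfig,
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """In-memory dataset: labeled images, their mask stacks, unlabeled images."""
    imgs, mask_stacks = [], {name: [] for name in LESIONS}
    for i in range(cfg.n_labeled):
        img, masks = generate_sample(cfg, _sample_rng(cfg.seed, "labeled", i))
        imgs.append(img)
        for name in LESIONS:
            mask_stacks[name].append(masks[name])
    unlabeled = [
        generate_unlabeled_sample(cfg, _sample_rng(cfg.seed, "unlabeled", i))
        for i in range(cfg.n_unlabeled)
    ]
    h = cfg.image_size
    labeled_arr = np.stack(imgs) if imgs else np.zeros((0, 3, h, h))
    unlabeled_arr = np.stack(unlabeled) if unlabeled else np.zeros((0, 3, h, h))
    masks_arr = {
        name: (np.stack(v) if v else np.zeros((0, h, h), dtype=np.uint8))
        for name, v in mask_stacks.items()
    }
    return labeled_arr, masks_arr, unlabeled_arr


def generate_dataset(cfg: SyntheticConfig, out_dir) -> DatasetManifest:
    """Write a labeled + unlabeled synthetic pool to disk and manifest it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(cfg.n_labeled):
        img, masks = generate_sample(cfg, _sample_rng(cfg.seed, "labeled", i))
        sid = f"lab{i:04d}"
        img_path = out / f"{sid}.png"
        save_image(img_path, img)
        mask_paths = {}
        for name in LESIONS:
            mpath = out / f"{sid}_{name}.png"
            save_mask(mpath, masks[name])
            mask_paths[name] = str(mpath)
        entries.append(ManifestEntry(sid, str(img_path), mask_paths, True, "train"))
    for i in range(cfg.n_unlabeled):
        img = generate_unlabeled_sample(cfg, _sample_rng(cfg.seed, "unlabeled", i))
        sid = f"unl{i:04d}"
        img_path = out / f"{sid}.png"
        save_image(img_path, img)
        entries.append(ManifestEntry(sid, str(img_path), {}, False, "unlabeled"))
    return DatasetManifest(
        entries,
        {
            "generator": "retseg.synthetic",
            "seed": cfg.seed,
            "image_size": cfg.image_size,
        },
    )
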