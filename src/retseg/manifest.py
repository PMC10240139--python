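"""Dataset manifests: discovery, validation, deterministic splitting.

A manifest is a table of records binding an image file to its optional
per-lesion mask files, a labeled flag, and a split tag (train / val / test /
unlabeled).  Manifests serialise losslessly to CSV and JSON and are the unit
every pipeline stage exchanges.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import LESIONS

logger = logging.getLogger("retseg")

SPLITS = ("train", "val", "test", "unlabeled")
IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")

__all__ = [
    "ManifestEntry",
    "DatasetManifest",
    "SplitSpec",
    "build_manifest",
    "split_manifest",
    "merge_manifests",
]


@dataclass
class ManifestEntry:
    id: str
    image_path: str
    mask_paths: dict[str, str] = field(default_factory=dict)
    labeled: bool = False
    split: str = "unlabeled"

    def validate(self, lesions: tuple[str, ...] = LESIONS) -> None:
        if self.split not in SPLITS:
            raise ValueError(f"entry {self.id}: unknown split {self.split!r}")
        has_all = all(l in self.mask_paths for l in lesions)
        if self.labeled != has_all:
            raise ValueError(
                f"entry {self.id}: labeled={self.labeled} inconsistent with "
                f"masks present for {sorted(self.mask_paths)}"
            )
        if self.split == "unlabeled" and self.labeled:
            raise ValueError(f"entry {self.id}: unlabeled split but labeled=True")


class DatasetManifest:
    """Ordered, validated collection of :class:`ManifestEntry`."""

    def __init__(self, entries, metadata: dict | None = None):
        self.entries: list[ManifestEntry] = list(entries)
        self.metadata: dict = metadata or {}
        self.validate()

    def validate(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate manifest ids: {dup}")
        for e in self.entries:
            e.validate()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            [e for e in self.entries if e.split == split], dict(self.metadata)
        )

    @property
    def labeled_entries(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.labeled]

    def split_sizes(self) -> dict[str, int]:
        sizes = {s: 0 for s in SPLITS}
        for e in self.entries:
            sizes[e.split] += 1
        return sizes

    # -- serialisation -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"id": e.id, "image_path": e.image_path}
            for l in LESIONS:
                row[f"{l}_mask"] = e.mask_paths.get(l, "")
            row["labeled"] = e.labeled
            row["split"] = e.split
            rows.append(row)
        cols = ["id", "image_path"] + [f"{l}_mask" for l in LESIONS] + ["labeled", "split"]
        return pd.DataFrame(rows, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        df = pd.read_csv(path, dtype={"id": str}, keep_default_na=False)
        entries = []
        for _, row in df.iterrows():
            masks = {l: row[f"{l}_mask"] for l in LESIONS if row[f"{l}_mask"]}
            entries.append(
                ManifestEntry(
                    id=row["id"],
                    image_path=row["image_path"],
                    mask_paths=masks,
                    labeled=str(row["labeled"]).lower() in ("true", "1"),
                    split=row["split"],
                )
            )
        return cls(entries)

    def to_json(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "entries": [
                {
                    "id": e.id,
                    "image_path": e.image_path,
                    "mask_paths": e.mask_paths,
                    "labeled": e.labeled,
                    "split": e.split,
                }
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DatasetManifest":
        with open(path) as fh:
            payload = json.load(fh)
        entries = [ManifestEntry(**d) for d in payload["entries"]]
        return cls(entries, payload.get("metadata", {}))


@dataclass(frozen=True)
class SplitSpec:
    """Deterministic three-way split.

    Sizes: ``n_val = round(N * f_val)`` and ``n_test = round(N * f_test)``
    (numpy round, half to even), with the remainder going to train.  For the
    1842-image labeled pool at fractions (0.70, 0.05, 0.25) this yields
    (1290, 92, 460).  Assignment is a PCG64-seeded shuffle followed by
    contiguous slicing, so the same (entries, spec) pair always produces the
    identical partition.
    """

    fractions: tuple[float, float, float] = (0.70, 0.05, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be three non-negative reals")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")

    def sizes(self, n: int) -> tuple[int, int, int]:
        n_val = int(np.round(n * self.fractions[1]))
        n_test = int(np.round(n * self.fractions[2]))
        n_train = n - n_val - n_test
        if n_train < 0:  # rounding overshoot on tiny n
            n_test += n_train
            n_train = 0
        return n_train, n_val, n_test


def split_manifest(manifest: DatasetManifest, spec: SplitSpec) -> DatasetManifest:
    """Partition a fully labeled manifest into train/val/test."""
    unlabeled = [e.id for e in manifest if not e.labeled]
    if unlabeled:
        raise ValueError(f"cannot split: unlabeled entries present {unlabeled[:5]}")
    n = len(manifest)
    n_train, n_val, n_test = spec.sizes(n)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    tags = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    entries = []
    for pos, idx in enumerate(order):
        src = manifest.entries[idx]
        entries.append(
            ManifestEntry(src.id, src.image_path, dict(src.mask_paths), True, tags[pos])
        )
    entries.sort(key=lambda e: e.id)
    meta = dict(manifest.metadata)
    meta["split"] = {
        "fractions": list(spec.fractions),
        "seed": spec.seed,
        "prng": "numpy-PCG64",
        "sizes": {"train": n_train, "val": n_val, "test": n_test},
    }
    return DatasetManifest(entries, meta)


def merge_manifests(*manifests: DatasetManifest) -> DatasetManifest:
    """Concatenate manifests into one pool; ids must stay unique."""
    entries: list[ManifestEntry] = []
    for m in manifests:
        entries.extend(m.entries)
    return DatasetManifest(entries)


def build_manifest(
    root_dir,
    lesions: tuple[str, ...] = LESIONS,
    mask_template: str = "{id}_{lesion}",
) -> DatasetManifest:
    """Discover images and associated masks under ``root_dir``.

    A file whose stem matches ``mask_template`` for some lesion is a mask;
    every other image file is a sample.  Entries are sorted by id.  A mask
    with no matching image is a hard error; an image with a proper subset of
    the lesion masks is kept unlabeled with a logged warning.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"not a directory: {root}")
    suffixes = {}
    for l in lesions:
        suffixes[mask_template.format(id="", lesion=l)] = l
    images: dict[str, Path] = {}
    masks: dict[str, dict[str, Path]] = {}
    for p in sorted(root.rglob("*")):
        if p.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        stem = p.stem
        matched = None
        for suffix, lesion in suffixes.items():
            if stem.endswith(suffix):
                matched = (stem[: len(stem) - len(suffix)], lesion)
                break
        if matched:
            masks.setdefault(matched[0], {})[matched[1]] = p
        else:
            images[stem] = p
    orphans = sorted(set(masks) - set(images))
    if orphans:
        raise ValueError(f"mask files without a matching image: {orphans[:5]}")
    entries = []
    for image_id in sorted(images):
        mask_paths = {l: str(p) for l, p in masks.get(image_id, {}).items()}
        labeled = all(l in mask_paths for l in lesions)
        if mask_paths and not labeled:
            missing = [l for l in lesions if l not in mask_paths]
            logger.warning(
                "image %s has masks %s but is missing %s; treating as unlabeled",
                image_id,
                sorted(mask_paths),
                missing,
            )
        entries.append(
            ManifestEntry(
                id=image_id,
                image_path=str(images[image_id]),
                mask_paths=mask_paths,
                labeled=labeled,
                split="train" if labeled else "unlabeled",
            )
        )
    return DatasetManifest(entries, {"root": str(root)})
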