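"""Desk-scale experiment harnesses on synthetic data.

Three protocols, mirroring the analyses usually run for multi-task
semi-supervised segmentation:

* auxiliary-task ablation: 0-3 auxiliary segmentation decoders, each under
  purely supervised (SL) and semi-supervised (SSL, with reconstruction
  pretraining) regimes;
* unlabeled-data sweep: how the primary lesion's dice responds to the size
  of the unlabeled pool used for pretraining (0 = supervised only);
* cross-dataset robustness: train on a source generator configuration,
  evaluate on a shifted target configuration, optionally mixing a fraction
  of target-domain images into training.

Every cell is fully specified by its (variable value, seed) pair plus the
grid's base configurations; results are tidy DataFrames carrying a config
hash so reruns are identifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import MetricsReport, evaluate
from .network import LESIONS, NetworkConfig
from .synthetic import SyntheticConfig, generate_arrays
from .trainer import ArrayDataset, LesionSegmentationModel, TrainConfig

__all__ = [
    "ExperimentGrid",
    "desk_benchmark_grid",
    "run_auxiliary_ablation",
    "run_unlabeled_sweep",
    "run_cross_dataset",
]

# fixed priority for choosing auxiliaries at k < 3 so cells stay comparable
AUX_PRIORITY = ("EX", "SE", "MA", "HE")


@dataclass
class ExperimentGrid:
    """Shared configuration for one experiment family."""

    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    network_config: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(depth=3, base_channels=4)
    )
    train_config: TrainConfig = field(default_factory=TrainConfig.desk_scale)

    def config_hash(self) -> str:
        payload = {
            "synthetic": repr(self.synthetic_config),
            "network": repr(self.network_config),
            "train": repr(self.train_config),
            "seeds": list(self.seeds),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def desk_benchmark() -> tuple[SyntheticConfig, NetworkConfig, TrainConfig]:
    """The default desk-scale benchmark: 128-px synthetic fundus images,
    40 labeled / 200 unlabeled, a tiny depth-3 network, short two-phase
    training with hard exudates (the most learnable lesion) as primary."""
    return (
        SyntheticConfig(image_size=128, n_labeled=40, n_unlabeled=200),
        NetworkConfig(depth=3, base_channels=4),
        TrainConfig.desk_scale(epochs_unsup=2, epochs_sup=10, primary="EX"),
    )


def desk_benchmark_grid(seeds: tuple[int, ...] = (0, 1, 2, 3, 4)) -> ExperimentGrid:
    """Trend-check conditions: small 64-px images so multi-seed sweeps stay cheap."""
    return ExperimentGrid(
        seeds=seeds,
        synthetic_config=SyntheticConfig(image_size=64, n_labeled=28, n_unlabeled=60),
        network_config=NetworkConfig(depth=3, base_channels=4),
        train_config=TrainConfig.desk_scale(
            epochs_unsup=4, epochs_sup=15, primary="EX"
        ),
    )


def _split_labeled(
    imgs: np.ndarray, masks: dict[str, np.ndarray]
) -> tuple[ArrayDataset, ArrayDataset]:
    n_val = max(2, int(round(0.15 * len(imgs))))
    train = ArrayDataset(
        imgs[:-n_val], {k: v[:-n_val] for k, v in masks.items()}
    )
    val = ArrayDataset(imgs[-n_val:], {k: v[-n_val:] for k, v in masks.items()})
    return train, val


def _fit_cell(
    synth_cfg: SyntheticConfig,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    pretrain: bool,
):
    imgs, masks, unl = generate_arrays(synth_cfg)
    train, val = _split_labeled(imgs, masks)
    unlabeled = ArrayDataset(unl) if (pretrain and len(unl)) else None
    model = LesionSegmentationModel(train, val, unlabeled, net_cfg, train_cfg)
    return model.fit()


def auxiliary_lesions(primary: str, k: int) -> tuple[str, ...]:
    """The first ``k`` non-primary lesions in the fixed priority order."""
    if not 0 <= k <= 3:
        raise ValueError("k must be between 0 and 3")
    pool = [l for l in AUX_PRIORITY if l != primary]
    return tuple(pool[:k])


def run_auxiliary_ablation(
    grid: ExperimentGrid,
    ks: tuple[int, ...] = (0, 1, 2, 3),
    regimes: tuple[str, ...] = ("SL", "SSL"),
) -> pd.DataFrame:
    """Primary-task dice as a function of the number of auxiliary decoders.

    For each k the network carries 1 + k segmentation decoders (primary
    first) plus the reconstruction decoder; SSL cells pretrain on the
    unlabeled pool, SL cells do not.
    """
    rows = []
    primary = grid.train_config.primary
    for k in ks:
        lesions = (primary,) + auxiliary_lesions(primary, k)
        net_cfg = replace(grid.network_config, lesions=lesions)
        for regime in regimes:
            for seed in grid.seeds:
                res = _fit_cell(
                    replace(grid.synthetic_config, seed=seed),
                    net_cfg,
                    replace(grid.train_config, seed=seed),
                    pretrain=(regime == "SSL"),
                )
                rows.append(
                    {
                        "experiment": "auxiliary_ablation",
                        "n_auxiliary": k,
                        "regime": regime,
                        "seed": seed,
                        "primary": primary,
                        "best_val_dice": res.best_val_dice,
                        "config_hash": grid.config_hash(),
                    }
                )
    return pd.DataFrame(rows)


def run_unlabeled_sweep(
    grid: ExperimentGrid, n_unlabeled_values: tuple[int, ...] = (0, 20, 60)
) -> pd.DataFrame:
    """Primary-task dice as a function of the unlabeled pool size."""
    rows = []
    for n_unl in n_unlabeled_values:
        for seed in grid.seeds:
            res = _fit_cell(
                replace(grid.synthetic_config, seed=seed, n_unlabeled=n_unl),
                grid.network_config,
                replace(grid.train_config, seed=seed),
                pretrain=(n_unl > 0),
            )
            rows.append(
                {
                    "experiment": "unlabeled_sweep",
                    "n_unlabeled": n_unl,
                    "seed": seed,
                    "primary": grid.train_config.primary,
                    "best_val_dice": res.best_val_dice,
                    "config_hash": grid.config_hash(),
                }
            )
    return pd.DataFrame(rows)


def domain_shifted(cfg: SyntheticConfig) -> SyntheticConfig:
    """Default target-domain shift: lower contrast, more pixel noise."""
    return replace(cfg, contrast=min(1.0, cfg.contrast * 0.7), noise_sd=cfg.noise_sd * 1.5)


def run_cross_dataset(
    source_cfg: SyntheticConfig,
    target_cfg: SyntheticConfig,
    mix_fraction: float,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    n_eval: int = 12,
) -> tuple[MetricsReport, dict]:
    """Train on the source domain, evaluate on a shifted target domain.

    ``mix_fraction`` of the target training pool (rounded half-to-even) is
    added to the supervised training set; the evaluation pool comes from an
    independent seed stream, so no evaluated image is ever trained on.
    """
    if not 0.0 <= mix_fraction < 1.0:
        raise ValueError("mix_fraction must lie in [0, 1)")
    if source_cfg == target_cfg:
        raise ValueError("source and target configurations must differ")
    src_imgs, src_masks, src_unl = generate_arrays(source_cfg)
    tgt_imgs, tgt_masks, _ = generate_arrays(replace(target_cfg, n_unlabeled=0))
    n_mix = int(np.round(mix_fraction * len(tgt_imgs)))
    eval_cfg = replace(
        target_cfg, seed=target_cfg.seed + 7919, n_labeled=n_eval, n_unlabeled=0
    )
    ev_imgs, ev_masks, _ = generate_arrays(eval_cfg)

    train, val = _split_labeled(src_imgs, src_masks)
    if n_mix:  # mixed target images join the training set only, never val
        train = ArrayDataset(
            np.concatenate([train.images, tgt_imgs[:n_mix]]),
            {
                k: np.concatenate([train.masks[k], tgt_masks[k][:n_mix]])
                for k in train.masks
            },
        )
    unlabeled = ArrayDataset(src_unl) if len(src_unl) else None
    model = LesionSegmentationModel(train, val, unlabeled, net_cfg, train_cfg)
    res = model.fit()
    report = evaluate(res.network, ev_imgs, ev_masks)
    info = {
        "n_source_train": int(len(src_imgs)),
        "n_target_mixed": int(n_mix),
        "n_target_eval": int(len(ev_imgs)),
        "mix_fraction": float(mix_fraction),
        "best_val_dice": res.best_val_dice,
    }
    return report, info
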