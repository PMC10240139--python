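"""Two-phase semi-supervised training.

Phase 1 (unsupervised): the shared encoder and the reconstruction decoder
are optimised for mean-squared reconstruction error on the unlabeled pool.
Phase 2 (supervised): the encoder and the four segmentation decoders are
optimised for the weighted multi-task dice objective, with the designated
primary lesion weighted ``beta`` against the auxiliaries' ``1 - beta``; one
model is trained per primary lesion, all starting from the same pretrained
snapshot.

The module exposes both the phase functions and a statsmodels-style
``LesionSegmentationModel`` / ``SegmentationResults`` pair wrapping them.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import losses as L
from .losses import LossWeights
from .metrics import MetricsReport, dice_score, evaluate
from .network import LESIONS, MultiDecoderUNet, NetworkConfig, build_network
from .nn import SGD

logger = logging.getLogger("retseg")

__all__ = [
    "ArrayDataset",
    "TrainConfig",
    "TrainState",
    "pretrain_reconstruction",
    "train_supervised",
    "train_all_primaries",
    "LesionSegmentationModel",
    "SegmentationResults",
    "dataset_from_manifest",
    "state_hash",
]


@dataclass
class ArrayDataset:
    """In-memory image stack with optional per-lesion mask stacks."""

    images: np.ndarray  # (N, 3, H, W) in [0, 1]
    masks: dict[str, np.ndarray] | None = None  # lesion -> (N, H, W) in {0,1}

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 4:
            raise ValueError("images must be (N, C, H, W)")
        if self.masks is not None:
            for name, m in self.masks.items():
                if m.shape != (len(self), *self.images.shape[2:]):
                    raise ValueError(f"mask stack {name} misaligned with images")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def labeled(self) -> bool:
        return self.masks is not None


def dataset_from_manifest(manifest, split: str | None = None) -> ArrayDataset:
    """Load the images (and masks, when labeled) of a manifest split."""
    from .images import load_image, load_mask

    entries = list(manifest) if split is None else list(manifest.subset(split))
    if not entries:
        raise ValueError(f"no entries in split {split!r}")
    images = np.stack([load_image(e.image_path) for e in entries])
    if all(e.labeled for e in entries):
        masks = {
            name: np.stack([load_mask(e.mask_paths[name]) for e in entries])
            for name in LESIONS
        }
    else:
        masks = None
    return ArrayDataset(images, masks)


@dataclass
class TrainConfig:
    """Optimisation settings for both phases.

    Defaults mirror full-scale training (SGD, learning rate 1e-4, batch 16);
    ``desk_scale`` returns settings sized for the small synthetic benchmark.
    """

    batch_size: int = 16
    learning_rate: float = 1e-4
    momentum: float = 0.0
    epochs_unsup: int = 20
    epochs_sup: int = 50
    weights: LossWeights = field(default_factory=LossWeights)
    primary: str = "EX"
    seed: int = 0
    supervised_recon: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Settings for tiny networks on the synthetic benchmark."""
        base = dict(
            batch_size=8,
            learning_rate=0.2,
            momentum=0.9,
            epochs_unsup=4,
            epochs_sup=20,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainState:
    """Outcome of a training phase."""

    network: MultiDecoderUNet
    history: pd.DataFrame
    config: TrainConfig
    phase: str
    best_state: dict | None = None
    best_val_dice: float | None = None

    def epoch_means(self, column: str) -> pd.Series:
        return self.history.groupby("epoch")[column].mean()


def state_hash(net_or_state) -> str:
    """Content hash of a parameter state (for phase-isolation assertions)."""
    state = net_or_state.state_dict() if hasattr(net_or_state, "state_dict") else net_or_state
    digest = hashlib.sha256()
    for key in sorted(state):
        digest.update(key.encode())
        digest.update(np.ascontiguousarray(state[key]).tobytes())
    return digest.hexdigest()


def _batches(n: int, batch_size: int, rng: np.random.Generator, drop_last: bool):
    order = rng.permutation(n)
    n_full = n // batch_size
    if n_full == 0:
        if drop_last:
            logger.warning("fewer samples (%d) than batch size; using one batch", n)
        yield order
        return
    for b in range(n_full):
        yield order[b * batch_size : (b + 1) * batch_size]
    if not drop_last and n % batch_size:
        yield order[n_full * batch_size :]


def _check_finite(value: float, phase: str, step: int) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite loss ({value}) in {phase} phase at step {step}; "
            "lower the learning rate or inspect the input data"
        )


def pretrain_reconstruction(
    net: MultiDecoderUNet, unlabeled: ArrayDataset, cfg: TrainConfig
) -> TrainState:
    """Unsupervised phase: minimise MSE reconstruction on the unlabeled pool.

    Only the encoder and the reconstruction decoder receive updates; every
    segmentation decoder's parameters are left bit-identical.
    """
    if len(unlabeled) == 0:
        raise ValueError("unlabeled pool is empty")
    if net.recon_decoder is None:
        raise ValueError("network has no reconstruction decoder")
    params = net.encoder_parameters() + net.recon_parameters()
    opt = SGD(params, lr=cfg.learning_rate, momentum=cfg.momentum)
    rows = []
    step = 0
    net.train()
    for epoch in range(cfg.epochs_unsup):
        rng = np.random.default_rng([cfg.seed, 17, epoch])
        for idx in _batches(len(unlabeled), cfg.batch_size, rng, drop_last=True):
            x = unlabeled.images[idx]
            skips, z = net.encode(x)
            recon = net.recon_decoder(z, skips).sigmoid()
            loss = L.reconstruction_loss(x, recon)
            _check_finite(loss.item(), "unsupervised", step)
            net.zero_grad()
            loss.backward()
            opt.step()
            rows.append({"epoch": epoch, "step": step, "L_rec": loss.item()})
            step += 1
    history = pd.DataFrame(rows, columns=["epoch", "step", "L_rec"])
    return TrainState(net, history, cfg, phase="unsupervised")


def refresh_bn_stats(
    net: MultiDecoderUNet, images: np.ndarray, include_recon: bool = True
) -> None:
    """Recompute batch-norm running statistics from a reference batch.

    With few, large SGD steps the exponentially averaged statistics lag far
    behind the current parameters, which makes evaluation-mode forward passes
    unrepresentative; setting the buffers to the statistics of one reference
    batch under the final parameters fixes that.  The reconstruction decoder
    is skipped when it is not part of the phase's update set.
    """
    from .nn.layers import BatchNorm2d

    bns = [m for m in net.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    was_training = net.training
    net.train()
    skips, z = net.encode(images)
    for dec in net.seg_decoders:
        dec(z, skips)
    if include_recon and net.recon_decoder is not None:
        net.recon_decoder(z, skips)
    for bn, m in zip(bns, saved):
        bn.momentum = m
    if not was_training:
        net.eval()


def _val_dice(net: MultiDecoderUNet, val: ArrayDataset, primary: str) -> float:
    probs = net.predict_proba(val.images)[primary]
    preds = (probs.reshape(val.masks[primary].shape) >= 0.5).astype(np.uint8)
    return float(
        np.mean([dice_score(p, g) for p, g in zip(preds, val.masks[primary])])
    )


def train_supervised(
    net: MultiDecoderUNet,
    train: ArrayDataset,
    val: ArrayDataset | None,
    cfg: TrainConfig,
) -> TrainState:
    """Supervised phase: weighted multi-task dice (+ optional reconstruction).

    Updates the encoder and all segmentation decoders; the reconstruction
    decoder joins the update set only when ``cfg.supervised_recon`` is true.
    The best-validation-dice parameter snapshot is retained.
    """
    if not train.labeled:
        raise ValueError("supervised training requires masks on every entry")
    lesions = net.config.lesions
    if cfg.primary not in lesions:
        raise ValueError(f"primary {cfg.primary!r} not among decoders {lesions}")
    params = net.encoder_parameters() + net.seg_parameters()
    use_recon = cfg.supervised_recon and net.recon_decoder is not None
    if use_recon:
        params += net.recon_parameters()
    opt = SGD(params, lr=cfg.learning_rate, momentum=cfg.momentum)
    w = cfg.weights
    rows = []
    best_state = None
    best_val = -np.inf
    step = 0
    for epoch in range(cfg.epochs_sup):
        net.train()
        rng = np.random.default_rng([cfg.seed, 29, epoch])
        for idx in _batches(len(train), cfg.batch_size, rng, drop_last=True):
            x = train.images[idx]
            skips, z = net.encode(x)
            task_losses = {}
            for name, dec in zip(lesions, net.seg_decoders):
                logits = dec(z, skips)
                gt = train.masks[name][idx][:, None, :, :]
                task_losses[name] = L.dice_loss(logits, gt, w.epsilon)
            seg = L.segmentation_loss(task_losses, cfg.primary, w.beta)
            if use_recon:
                recon = net.recon_decoder(z, skips).sigmoid()
                total = L.total_loss(L.reconstruction_loss(x, recon), seg, w.alpha)
                rec_val = L.reconstruction_loss(x, recon).item()
            else:
                total = seg
                rec_val = np.nan
            _check_finite(total.item(), "supervised", step)
            net.zero_grad()
            total.backward()
            opt.step()
            row = {"epoch": epoch, "step": step, "L_rec": rec_val, "total": total.item()}
            row.update({f"L_{n}": t.item() for n, t in task_losses.items()})
            rows.append(row)
            step += 1
        if val is not None:
            ref = train.images[: min(len(train), 2 * cfg.batch_size)]
            refresh_bn_stats(net, ref, include_recon=use_recon)
            vd = _val_dice(net, val, cfg.primary)
            if vd > best_val:
                best_val = vd
                best_state = net.state_dict()
    history = pd.DataFrame(rows)
    state = TrainState(net, history, cfg, phase="supervised")
    if val is not None:
        state.best_state = best_state
        state.best_val_dice = best_val
        net.load_state_dict(best_state)  # leave the network at its best epoch
    return state


def train_all_primaries(
    train: ArrayDataset,
    val: ArrayDataset | None,
    unlabeled: ArrayDataset | None,
    cfg: TrainConfig,
    network_config: NetworkConfig | None = None,
) -> dict[str, TrainState]:
    """Train one model per lesion from a single shared pretrained snapshot."""
    net_cfg = network_config or NetworkConfig()
    base = build_network(net_cfg, seed=cfg.seed)
    if unlabeled is not None and len(unlabeled) > 0 and cfg.epochs_unsup > 0:
        pretrain_reconstruction(base, unlabeled, cfg)
    snapshot = base.state_dict()
    registry: dict[str, TrainState] = {}
    for lesion in net_cfg.lesions:
        net = build_network(net_cfg, seed=cfg.seed)
        net.load_state_dict(snapshot)
        registry[lesion] = train_supervised(
            net, train, val, replace(cfg, primary=lesion)
        )
    return registry


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class LesionSegmentationModel:
    """Semi-supervised multi-task segmentation model bound to its data.

    Parameters
    ----------
    train, val
        Labeled :class:`ArrayDataset` splits (val may be None).
    unlabeled
        Image-only pool for the unsupervised phase (may be None for purely
        supervised training).
    network_config, train_config
        Topology and optimisation settings; defaults are full-scale.
    """

    def __init__(
        self,
        train: ArrayDataset,
        val: ArrayDataset | None = None,
        unlabeled: ArrayDataset | None = None,
        network_config: NetworkConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.train_data = train
        self.val_data = val
        self.unlabeled_data = unlabeled
        self.network_config = network_config or NetworkConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_manifest(
        cls,
        manifest,
        network_config: NetworkConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "LesionSegmentationModel":
        """Build from a split manifest (train/val/test plus unlabeled pool)."""
        sizes = manifest.split_sizes()
        train = dataset_from_manifest(manifest, "train")
        val = dataset_from_manifest(manifest, "val") if sizes["val"] else None
        unlabeled = (
            dataset_from_manifest(manifest, "unlabeled") if sizes["unlabeled"] else None
        )
        return cls(train, val, unlabeled, network_config, train_config)

    def fit(self) -> "SegmentationResults":
        cfg = self.train_config
        net = build_network(self.network_config, seed=cfg.seed)
        pretrain_state = None
        if (
            self.unlabeled_data is not None
            and len(self.unlabeled_data) > 0
            and cfg.epochs_unsup > 0
        ):
            pretrain_state = pretrain_reconstruction(net, self.unlabeled_data, cfg)
        sup_state = train_supervised(net, self.train_data, self.val_data, cfg)
        return SegmentationResults(self, net, pretrain_state, sup_state)


class SegmentationResults:
    """Fitted model: trained parameters, loss history, and evaluation."""

    def __init__(self, model, network, pretrain_state, train_state):
        self.model = model
        self.network = network
        self.pretrain_state = pretrain_state
        self.train_state = train_state

    @property
    def best_val_dice(self) -> float | None:
        return self.train_state.best_val_dice

    @property
    def loss_history(self) -> pd.DataFrame:
        frames = []
        if self.pretrain_state is not None:
            frames.append(self.pretrain_state.history.assign(phase="unsupervised"))
        frames.append(self.train_state.history.assign(phase="supervised"))
        return pd.concat(frames, ignore_index=True)

    def predict_proba(self, images) -> dict[str, np.ndarray]:
        return self.network.predict_proba(images)

    def evaluate(
        self, images, masks: Mapping[str, np.ndarray], threshold: float = 0.5
    ) -> MetricsReport:
        return evaluate(self.network, images, masks, threshold=threshold)

    def save(self, path) -> None:
        from .checkpoint import save_checkpoint

        save_checkpoint(self.network, path)

    def summary(self) -> str:
        cfg = self.model.train_config
        hist = self.train_state.history
        lines = [
            "Semi-supervised multi-decoder U-Net",
            "=" * 48,
            f"primary lesion        {cfg.primary}",
            f"decoders              {', '.join(self.network.config.lesions)}"
            + (" + reconstruction" if self.network.recon_decoder else ""),
            f"parameters            {self.network.n_parameters():,d}",
            f"alpha / beta          {cfg.weights.alpha} / {cfg.weights.beta}",
            f"optimizer             SGD(lr={cfg.learning_rate}, "
            f"momentum={cfg.momentum}), batch {cfg.batch_size}",
        ]
        if self.pretrain_state is not None:
            pre = self.pretrain_state.epoch_means("L_rec")
            lines.append(
                f"unsup phase           {len(pre)} epochs, "
                f"L_rec {pre.iloc[0]:.4f} -> {pre.iloc[-1]:.4f}"
            )
        totals = hist.groupby("epoch")["total"].mean()
        lines.append(
            f"sup phase             {len(totals)} epochs, "
            f"loss {totals.iloc[0]:.4f} -> {totals.iloc[-1]:.4f}"
        )
        if self.best_val_dice is not None:
            lines.append(f"best val dice ({cfg.primary})  {self.best_val_dice:.4f}")
        return "\n".join(lines)

    def plot_learning_curves(self, path=None):
        """Combined-loss learning curve per phase (matplotlib Figure)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        if self.pretrain_state is not None:
            pre = self.pretrain_state.epoch_means("L_rec")
            ax.plot(pre.index, pre.values, label="unsupervised L_rec")
        sup = self.train_state.epoch_means("total")
        ax.plot(sup.index, sup.values, label="supervised total loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
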