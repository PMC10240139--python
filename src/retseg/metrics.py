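"""Segmentation evaluation: dice, MAE, sensitivity, AUC-ROC, AUC-PR.

Dice and sensitivity are computed per image on masks thresholded at a fixed
probability cut-off and then averaged; MAE is the per-image mean absolute
difference between the probability map and the binary ground truth; the two
AUCs rank pixels pooled across the whole evaluation split, which keeps the
class prevalence of these highly imbalanced lesion maps represented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "dice_score",
    "mae",
    "sensitivity",
    "auc_roc",
    "auc_pr",
    "evaluate",
    "MetricsReport",
]


def _binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return a


def _check_shapes(a, b) -> None:
    if np.shape(a) != np.shape(b):
        raise ValueError(f"shape mismatch: {np.shape(a)} vs {np.shape(b)}")


def dice_score(pred_mask, gt) -> float:
    """2|P∩G| / (|P|+|G|); two empty masks count as perfect overlap (1.0)."""
    pred_mask, gt = _binary(pred_mask, "pred_mask"), _binary(gt, "gt")
    _check_shapes(pred_mask, gt)
    denom = pred_mask.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (pred_mask * gt).sum() / denom)


def mae(s_p, g) -> float:
    """Mean absolute pixel-wise error between probability map and ground truth."""
    s_p, g = np.asarray(s_p, dtype=float), np.asarray(g, dtype=float)
    _check_shapes(s_p, g)
    return float(np.abs(s_p - g).mean())


def sensitivity(pred_mask, gt) -> float:
    """Recall of ground-truth pixels: |P∩G| / |G|.  Undefined for empty G."""
    pred_mask, gt = _binary(pred_mask, "pred_mask"), _binary(gt, "gt")
    _check_shapes(pred_mask, gt)
    n_gt = gt.sum()
    if n_gt == 0:
        raise ValueError("sensitivity undefined for empty ground truth")
    return float((pred_mask * gt).sum() / n_gt)


def _pooled(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.concatenate([np.ravel(x) for x in np.atleast_1d(scores)]) \
        if isinstance(scores, (list, tuple)) else np.ravel(scores)
    l = np.concatenate([np.ravel(x) for x in np.atleast_1d(labels)]) \
        if isinstance(labels, (list, tuple)) else np.ravel(labels)
    _check_shapes(s, l)
    if len(np.unique(l)) < 2:
        raise ValueError("AUC undefined: pooled pixels contain a single class")
    return s, l


def auc_roc(scores, labels) -> float:
    """Probability a random positive pixel outranks a random negative one."""
    s, l = _pooled(scores, labels)
    return float(roc_auc_score(l, s))


def auc_pr(scores, labels) -> float:
    """Area under precision-recall via step summation (average precision)."""
    s, l = _pooled(scores, labels)
    return float(average_precision_score(l, s))


@dataclass
class MetricsReport:
    """Per-lesion metric table plus the aggregation choices that produced it."""

    per_lesion: dict[str, dict[str, float | None]]
    n_images: int
    threshold: float
    pooled_auc: bool = True
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_lesion": self.per_lesion,
            "n_images": self.n_images,
            "threshold": self.threshold,
            "pooled_auc": self.pooled_auc,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        cols = ("dsc", "auc_roc", "auc_pr", "mae", "sensitivity")
        lines = ["lesion  " + "  ".join(f"{c:>11}" for c in cols)]
        for lesion, m in self.per_lesion.items():
            vals = "  ".join(
                f"{m[c]:>11.4f}" if m[c] is not None else f"{'--':>11}" for c in cols
            )
            lines.append(f"{lesion:<6}  {vals}")
        lines.append(f"(n={self.n_images} images, threshold={self.threshold})")
        return "\n".join(lines)


def evaluate(
    model, images, masks, threshold: float = 0.5, pool_images: bool = False
) -> MetricsReport:
    """Evaluate a network on an image stack with per-lesion ground truth.

    Parameters
    ----------
    model
        Anything with ``predict_proba(batch) -> {lesion: (N,1,H,W) probs}``.
    images
        Array (N, 3, H, W) in [0, 1].
    masks
        Mapping lesion name -> binary array (N, H, W).
    threshold
        Probability cut-off for binarising predictions (dice/sensitivity).
    pool_images
        When true, dice/MAE/sensitivity are computed once over all pixels
        pooled across the split instead of per image then averaged.
    """
    images = np.asarray(images)
    probs = model.predict_proba(images)
    report: dict[str, dict[str, float | None]] = {}
    notes: list[str] = []
    for lesion, p in probs.items():
        if lesion not in masks:
            continue
        g = np.asarray(masks[lesion])
        p2 = p.reshape(g.shape)
        pred = (p2 >= threshold).astype(np.uint8)
        dscs, sens, maes = [], [], []
        if pool_images:
            dscs.append(dice_score(pred, g))
            maes.append(mae(p2, g))
            if g.sum() > 0:
                sens.append(sensitivity(pred, g))
        else:
            for i in range(g.shape[0]):
                dscs.append(dice_score(pred[i], g[i]))
                maes.append(mae(p2[i], g[i]))
                if g[i].sum() > 0:
                    sens.append(sensitivity(pred[i], g[i]))
        if not sens:
            notes.append(f"{lesion}: all ground-truth masks empty; SEN undefined")
        try:
            roc = auc_roc(p2, g)
            pr = auc_pr(p2, g)
        except ValueError:
            roc = pr = None
            notes.append(f"{lesion}: single-class pixels; AUCs undefined")
        report[lesion] = {
            "dsc": float(np.mean(dscs)),
            "auc_roc": roc,
            "auc_pr": pr,
            "mae": float(np.mean(maes)),
            "sensitivity": float(np.mean(sens)) if sens else None,
        }
    return MetricsReport(
        per_lesion=report,
        n_images=images.shape[0],
        threshold=threshold,
        pooled_auc=True,
        notes=notes,
    )
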