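"""Training objectives: MSE reconstruction, soft dice, and their combination.

The total objective is ``alpha * L_rec + L_seg`` where the segmentation part
weights the primary lesion against the three auxiliary ones:
``L_seg = beta * L_primary + (1 - beta) * sum(L_aux)``.

The dice denominator is implemented as ``sum(pred) + sum(gt)`` (standard
soft dice).  A literal set union there would score identical non-empty masks
at 2 rather than 1, contradicting the [0, 1] range of the dice coefficient,
so the sum form is used throughout losses and metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor

__all__ = [
    "LossWeights",
    "reconstruction_loss",
    "dice_loss",
    "segmentation_loss",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Trade-off parameters of the combined objective.

    alpha
        Weight of the reconstruction term; >= 0.  The MSE is a mean (not a
        sum) so alpha is independent of image resolution.
    beta
        Weight of the primary segmentation task in [0, 1]; the three
        auxiliary tasks share weight (1 - beta).
    epsilon
        Dice smoothing constant, applied to numerator and denominator alike
        so an empty prediction against an empty mask scores loss 0.
    """

    alpha: float = 1.0
    beta: float = 0.7
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _check_shapes(a, b) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def reconstruction_loss(x, x_hat) -> Tensor:
    """Mean squared error between an image batch and its reconstruction."""
    x, x_hat = as_tensor(x), as_tensor(x_hat)
    _check_shapes(x.data, x_hat.data)
    return ((x - x_hat) ** 2).mean()


def dice_loss(logits, gt, epsilon: float = 1e-6) -> Tensor:
    """Soft dice loss on sigmoid probabilities: 1 - (2*sum(p*g)+eps)/(sum(p)+sum(g)+eps)."""
    logits, gt = as_tensor(logits), as_tensor(gt)
    _check_shapes(logits.data, gt.data)
    p = logits.sigmoid()
    inter = (p * gt).sum()
    denom = p.sum() + gt.sum()
    return 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)


def segmentation_loss(
    task_losses: dict[str, Tensor], primary: str, beta: float
) -> Tensor:
    """Weight the primary task's loss against the auxiliary tasks'."""
    if primary not in task_losses:
        raise KeyError(f"unknown primary task {primary!r}; have {sorted(task_losses)}")
    aux = [v for k, v in task_losses.items() if k != primary]
    out = beta * task_losses[primary]
    if aux:
        aux_sum = aux[0]
        for a in aux[1:]:
            aux_sum = aux_sum + a
        out = out + (1.0 - beta) * aux_sum
    return out


def total_loss(rec_loss, seg_loss, alpha: float) -> Tensor:
    """Combined objective ``alpha * rec + seg``."""
    return alpha * as_tensor(rec_loss) + as_tensor(seg_loss)
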