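"""Plain stochastic gradient descent with optional classical momentum."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class SGD:
    """Updates only the parameters it was constructed with.

    Restricting the parameter list is how the two training phases isolate
    their update sets (encoder + reconstruction decoder in the unsupervised
    phase; encoder + segmentation decoders in the supervised phase).
    """

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            if self.momentum:
                v *= self.momentum
                v -= self.lr * p.grad
                p.data = p.data + v
            else:
                p.data = p.data - self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
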