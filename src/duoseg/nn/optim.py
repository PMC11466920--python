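"""Adam optimiser and the cosine learning-rate schedule used for training."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "cosine_lr"]


class Adam:
    """Adam with bias correction (Kingma & Ba); lr is mutable between steps."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_lr(epoch: int, total_epochs: int, lr: float, min_lr: float) -> float:
    """Cosine annealing from ``lr`` (epoch 0) to exactly ``min_lr`` (last epoch)."""
    if total_epochs <= 1:
        return lr
    t = epoch / (total_epochs - 1)
    return min_lr + (lr - min_lr) * 0.5 * (1.0 + np.cos(np.pi * t))
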