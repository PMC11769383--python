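"""Optimizers and learning-rate schedules for the numpy engine."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "Adam", "CosineAnnealingLR", "cosine_lr"]


class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam(AdamW):
    """Adam without weight decay (the MoNuSeg-preset optimizer)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr=lr, betas=betas, eps=eps, weight_decay=0.0)


def cosine_lr(epoch: int, total_epochs: int, lr_max: float, lr_min: float) -> float:
    """Cosine annealing from lr_max (epoch 0) to lr_min (final epoch)."""
    if total_epochs <= 1:
        return lr_max
    t = epoch / (total_epochs - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + np.cos(np.pi * t))


class CosineAnnealingLR:
    def __init__(self, optimizer, total_epochs: int, lr_min: float):
        self.opt = optimizer
        self.total = total_epochs
        self.lr_max = optimizer.lr
        self.lr_min = lr_min

    def set_epoch(self, epoch: int):
        self.opt.lr = cosine_lr(epoch, self.total, self.lr_max, self.lr_min)
        return self.opt.lr
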