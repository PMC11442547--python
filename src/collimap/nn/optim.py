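"""Adam optimiser and a reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .core import Param

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0


class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` after ``patience`` non-improving epochs.

    "Improvement" means the monitored loss decreasing by more than
    ``min_delta`` (absolute) below the best value seen so far; the patience
    counter resets both on improvement and after a reduction fires.
    """

    def __init__(self, optimizer: Adam, factor: float = 0.75, patience: int = 3,
                 min_delta: float = 1e-6):
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must be in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.num_bad = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, metric: float) -> bool:
        """Record an epoch's monitored loss; return True if the LR was cut."""
        if metric < self.best - self.min_delta:
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad >= self.patience:
            self.optimizer.lr *= self.factor
            self.num_bad = 0
            return True
        return False
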