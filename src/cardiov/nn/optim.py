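"""Adam optimizer and a reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    """Adam with optional L2 weight decay (added to the gradient)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
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
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Multiply lr by `factor` when the monitored value stops improving.

    After `max_reductions` consecutive reductions without any improvement the
    schedule asks for an early stop (`should_stop`).
    """

    def __init__(self, optimizer: Adam, factor: float = 0.3, patience: int = 3,
                 min_lr: float = 1e-5, max_reductions: int = 3):
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must be in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.max_reductions = max_reductions
        self.best = np.inf
        self.bad_epochs = 0
        self.reductions_since_improvement = 0
        self.should_stop = False

    def step(self, metric: float):
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
            self.reductions_since_improvement = 0
            return
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.optimizer.lr = max(self.min_lr, self.optimizer.lr * self.factor)
            self.bad_epochs = 0
            self.reductions_since_improvement += 1
            if self.reductions_since_improvement >= self.max_reductions:
                self.should_stop = True
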