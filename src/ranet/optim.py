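"""Optimisation: Adam and a plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias-corrected first/second moments (β₁=0.9, β₂=0.999)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Multiply the optimiser's learning rate by ``factor`` when the
    monitored loss fails to improve for ``patience`` consecutive epochs."""

    def __init__(self, optimizer: Adam, *, factor: float = 0.1,
                 patience: int = 10, min_lr: float = 1e-7,
                 threshold: float = 1e-8):
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must lie in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = np.inf
        self.num_bad_epochs = 0

    def step(self, metric: float) -> bool:
        """Returns True if the learning rate was reduced this call."""
        if metric < self.best - self.threshold:
            self.best = metric
            self.num_bad_epochs = 0
            return False
        self.num_bad_epochs += 1
        if self.num_bad_epochs > self.patience:
            new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
            reduced = new_lr < self.optimizer.lr
            self.optimizer.lr = new_lr
            self.num_bad_epochs = 0
            return reduced
        return False
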