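"""Optimizers and learning-rate scheduling for the training loop."""

from __future__ import annotations

import numpy as np


class Adamax:
    """Adamax: Adam variant with an infinity-norm second-moment estimate."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._u = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bias_corr = 1.0 - self.beta1 ** self.t
        for p, m, u in zip(self.params, self._m, self._u):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            p.data -= self.lr * m / (bias_corr * (u + self.eps))


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored quantity (lower is better)."""

    def __init__(self, optimizer: Adamax, factor: float = 0.5, patience: int = 3,
                 min_lr: float = 1e-6, threshold: float = 1e-4):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = np.inf
        self.stale = 0

    def step(self, metric: float):
        if metric < self.best - self.threshold:
            self.best = metric
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.stale = 0
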