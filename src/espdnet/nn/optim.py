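"""AdamW and a plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np


class AdamW:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            # decoupled weight decay
            p.data = p.data * (1.0 - self.lr * self.weight_decay)
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Halve the learning rate when a monitored score stops improving."""

    def __init__(self, optimizer: AdamW, mode: str = "max", patience: int = 5,
                 factor: float = 0.5, min_lr: float = 1e-7):
        self.opt = optimizer
        self.sign = 1.0 if mode == "max" else -1.0
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, score: float):
        if self.sign * score > self.best:
            self.best = self.sign * score
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
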