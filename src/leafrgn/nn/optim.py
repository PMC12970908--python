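"""Momentum stochastic gradient descent, the optimizer used throughout."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD"]


class SGD:
    """SGD with classical momentum: v <- m*v + g;  p <- p - lr*v."""

    def __init__(self, params, lr: float = 0.001, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v
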