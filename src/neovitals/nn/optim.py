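"""Stochastic gradient descent with classical momentum and step-decay schedules."""

from __future__ import annotations

import numpy as np


class SGD:
    """v <- mu*v - lr*g; p <- p + v over a list of (param, grad) pairs."""

    def __init__(self, params, lr: float, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        for (p, g), v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0


def step_decay_lr(lr_start: float, step: int, decay_every: int, factor: float = 10.0) -> float:
    """Learning rate after dropping by ``factor`` every ``decay_every`` steps.

    ``step`` counts completed units (epochs or iterations): the rate used
    during unit k is lr_start / factor**(k // decay_every).
    """
    return lr_start / factor ** (step // decay_every)
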