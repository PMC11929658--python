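"""Stochastic gradient descent with classical momentum and L2 weight decay."""

from __future__ import annotations

import numpy as np

from brainnext.nn.layers import Param


class SGDMomentum:
    """v <- momentum*v - lr*(grad + l2*param);  param <- param + v."""

    def __init__(self, params: list[Param], lr: float = 0.01,
                 momentum: float = 0.1, weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[:] = 0

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v
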