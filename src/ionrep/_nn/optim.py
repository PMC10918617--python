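"""Adam optimizer over :class:`~ionrep._nn.layers.Param` lists."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Standard Adam with bias correction.

    Defaults mirror the training recipe used throughout the package:
    lr 3e-4, beta1 0.5, beta2 0.99.
    """

    def __init__(self, params: list[Param], lr: float = 3e-4,
                 beta1: float = 0.5, beta2: float = 0.99, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (0.0 <= beta1 < 1.0 and 0.0 <= beta2 < 1.0):
            raise ValueError("momentum parameters must lie in [0, 1)")
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad ** 2
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
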