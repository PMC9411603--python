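"""Stochastic gradient descent with classical momentum."""
from __future__ import annotations

from .layers import Parameter


class SGD:
    """v ← μ·v − lr·∇w ;  w ← w + v  (momentum μ, learning rate lr)."""

    def __init__(self, parameters: list[Parameter], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 <= momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        self.parameters = parameters
        self.lr = lr
        self.momentum = momentum

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad[...] = 0

    def step(self) -> None:
        for p in self.parameters:
            p.velocity = self.momentum * p.velocity - self.lr * p.grad
            p.value += p.velocity
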