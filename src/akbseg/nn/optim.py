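"""Stochastic gradient descent with momentum and decoupled weight decay."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD"]


class SGD:
    def __init__(self, params, lr=0.001, momentum=0.9, weight_decay=0.0005):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def state_dict(self):
        return {"velocity": [v.copy() for v in self.velocity],
                "lr": self.lr, "momentum": self.momentum,
                "weight_decay": self.weight_decay}

    def load_state_dict(self, state):
        for v, s in zip(self.velocity, state["velocity"]):
            v[...] = s
        self.lr = state["lr"]
        self.momentum = state["momentum"]
        self.weight_decay = state["weight_decay"]
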