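from __future__ import annotations

import numpy as np

from .core import Parameter


class Adam:
    """Adam over the trainable parameters of a model.

    Frozen parameters and buffers are skipped entirely, so their values
    remain bit-identical across any number of steps.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {id(p): np.zeros_like(p.data) for p in params}
        self._v = {id(p): np.zeros_like(p.data) for p in params}

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p in self.params:
            if not p.trainable:
                continue
            m = self._m[id(p)]
            v = self._v[id(p)]
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
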