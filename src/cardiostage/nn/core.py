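from __future__ import annotations

import numpy as np


class Parameter:
    """A named tensor with a gradient slot.

    ``trainable`` distinguishes weights the optimizer updates from frozen
    weights; ``buffer`` marks state that is never optimized (batch-norm
    running statistics) and is always counted as non-trainable.
    """

    __slots__ = ("name", "data", "grad", "trainable", "buffer")

    def __init__(self, name: str, data: np.ndarray, trainable: bool = True,
                 buffer: bool = False):
        self.name = name
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)
        self.trainable = trainable and not buffer
        self.buffer = buffer

    @property
    def size(self) -> int:
        return int(self.data.size)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class: children list parameters and implement forward/backward."""

    name: str = ""

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def set_trainable(self, flag: bool) -> None:
        for p in self.params():
            if not p.buffer:
                p.trainable = flag


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # fix sign ambiguity for determinism
    if rows < cols:
        q = q.T
    return q[:rows, :cols]
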