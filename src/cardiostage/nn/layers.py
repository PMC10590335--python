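from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .core import Layer, Parameter, glorot_uniform


class Conv1d(Layer):
    """Same-padded 1-D convolution with dilation, stride 1.

    Input (B, L, C_in) -> output (B, L, C_out). The kernel width must be
    odd so that zero-padding of (k-1)/2 * dilation on each side preserves
    length. Forward uses a strided patch view; the input gradient is the
    transposed convolution, implemented as k shifted accumulations.
    """

    def __init__(self, name: str, c_in: int, c_out: int, kernel: int,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd")
        self.name = name
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.dilation = kernel, dilation
        rng = rng or np.random.default_rng(0)
        w = glorot_uniform(rng, (kernel, c_in, c_out), kernel * c_in, kernel * c_out)
        self.w = Parameter(f"{name}.w", w)
        self.b = Parameter(f"{name}.b", np.zeros(c_out))
        self._cache: tuple | None = None

    def params(self) -> list[Parameter]:
        return [self.w, self.b]

    @property
    def pad(self) -> int:
        return (self.kernel - 1) // 2 * self.dilation

    def _patches(self, xp: np.ndarray, length: int) -> np.ndarray:
        b_, _, c = xp.shape
        sb, sl, sc = xp.strides
        return as_strided(
            xp,
            shape=(b_, length, self.kernel, c),
            strides=(sb, sl, self.dilation * sl, sc),
            writeable=False,
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b_, length, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        patches = self._patches(xp, length)
        y = np.tensordot(patches, self.w.data, axes=([2, 3], [0, 1])) + self.b.data
        if train:
            self._cache = (patches, (b_, length))
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        patches, (b_, length) = self._cache
        self.w.grad += np.tensordot(patches, grad, axes=([0, 1], [0, 1]))
        self.b.grad += grad.sum(axis=(0, 1))
        dxp = np.zeros((b_, length + 2 * self.pad, self.c_in))
        for t in range(self.kernel):
            off = t * self.dilation
            dxp[:, off:off + length, :] += grad @ self.w.data[t].T
        return dxp[:, self.pad:self.pad + length, :]


class BatchNorm1d(Layer):
    """Batch normalization per channel over (batch, length).

    Keras-style exponential running statistics (momentum 0.99). A frozen
    batch-norm layer (``frozen = True``) runs in inference mode even
    during training and stops updating its running statistics — this is
    what keeps the encoder bit-identical during fine-tuning.
    """

    def __init__(self, name: str, channels: int, momentum: float = 0.99,
                 eps: float = 1e-3):
        self.name = name
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.running_mean = Parameter(f"{name}.running_mean", np.zeros(channels), buffer=True)
        self.running_var = Parameter(f"{name}.running_var", np.ones(channels), buffer=True)
        self.frozen = False
        self._cache: tuple | None = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def set_trainable(self, flag: bool) -> None:
        super().set_trainable(flag)
        self.frozen = not flag

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        use_batch_stats = train and not self.frozen
        if use_batch_stats:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean.data = m * self.running_mean.data + (1 - m) * mean
            self.running_var.data = m * self.running_var.data + (1 - m) * var
        else:
            mean, var = self.running_mean.data, self.running_var.data
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, use_batch_stats, x.shape[0] * x.shape[1])
        return self.gamma.data * xhat + self.beta.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, used_batch, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        dxhat = grad * self.gamma.data
        if not used_batch:
            return dxhat * inv_std
        s1 = dxhat.sum(axis=(0, 1))
        s2 = (dxhat * xhat).sum(axis=(0, 1))
        return (inv_std / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling by a factor of 2 along the time axis."""

    def __init__(self, name: str = "pool", factor: int = 2):
        self.name = name
        self.factor = factor
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b_, length, c = x.shape
        if length % self.factor:
            raise ValueError("length must be divisible by the pooling factor")
        xr = x.reshape(b_, length // self.factor, self.factor, c)
        idx = xr.argmax(axis=2)
        y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        b_, length, c = shape
        out = np.zeros((b_, length // self.factor, self.factor, c))
        np.put_along_axis(out, idx[:, :, None, :], grad[:, :, None, :], axis=2)
        return out.reshape(shape)


class Upsample1d(Layer):
    """Nearest-neighbour upsampling by a factor of 2 along the time axis."""

    def __init__(self, name: str = "up", factor: int = 2):
        self.name = name
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(x, self.factor, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b_, length, c = grad.shape
        return grad.reshape(b_, length // self.factor, self.factor, c).sum(axis=2)
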