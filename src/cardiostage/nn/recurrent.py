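from __future__ import annotations

import numpy as np

from .core import Layer, Parameter, glorot_uniform, orthogonal


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _LSTMDirection:
    """One direction of an LSTM, gate order (input, forget, cell, output).

    Kernel shapes follow the usual convention: input kernel (c_in, 4u),
    recurrent kernel (u, 4u), bias (4u,) with the forget-gate slice
    initialized to 1. Full backpropagation through time.
    """

    def __init__(self, name: str, c_in: int, units: int, rng: np.random.Generator):
        self.c_in, self.units = c_in, units
        u = units
        self.w = Parameter(f"{name}.w", glorot_uniform(rng, (c_in, 4 * u), c_in, 4 * u))
        self.u = Parameter(f"{name}.u", np.concatenate(
            [orthogonal(rng, u, u) for _ in range(4)], axis=1))
        bias = np.zeros(4 * u)
        bias[u:2 * u] = 1.0
        self.b = Parameter(f"{name}.b", bias)
        self._cache: dict | None = None

    def params(self) -> list[Parameter]:
        return [self.w, self.u, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b_, steps, _ = x.shape
        u = self.units
        h = np.zeros((b_, u))
        c = np.zeros((b_, u))
        hs = np.zeros((b_, steps, u))
        cache = {"x": x, "i": [], "f": [], "g": [], "o": [], "c": [], "h_prev": [], "c_prev": []}
        for t in range(steps):
            z = x[:, t] @ self.w.data + h @ self.u.data + self.b.data
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            if train:
                cache["h_prev"].append(h)
                cache["c_prev"].append(c)
            c = f * c + i * g
            h = o * np.tanh(c)
            hs[:, t] = h
            if train:
                for k, v in zip("ifgo", (i, f, g, o)):
                    cache[k].append(v)
                cache["c"].append(c)
        if train:
            self._cache = cache
        return hs

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cache = self._cache
        x = cache["x"]
        b_, steps, _ = x.shape
        u = self.units
        dx = np.zeros_like(x)
        dh_next = np.zeros((b_, u))
        dc_next = np.zeros((b_, u))
        dw = np.zeros_like(self.w.data)
        du = np.zeros_like(self.u.data)
        db = np.zeros_like(self.b.data)
        for t in reversed(range(steps)):
            i, f, g, o = (cache[k][t] for k in "ifgo")
            c = cache["c"][t]
            c_prev = cache["c_prev"][t]
            h_prev = cache["h_prev"][t]
            tc = np.tanh(c)
            dh = grad[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                axis=1,
            )
            dw += x[:, t].T @ dz
            du += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.w.data.T
            dh_next = dz @ self.u.data.T
            dc_next = dc * f
        self.w.grad += dw
        self.u.grad += du
        self.b.grad += db
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM; concatenates forward and backward outputs.

    (B, T, c_in) -> (B, T, 2*units). The whole night is available at
    scoring time, so an offline bidirectional pass is appropriate.
    """

    def __init__(self, name: str, c_in: int, units: int,
                 rng: np.random.Generator | None = None):
        self.name = name
        self.units = units
        rng = rng or np.random.default_rng(0)
        self.fwd = _LSTMDirection(f"{name}.fwd", c_in, units, rng)
        self.bwd = _LSTMDirection(f"{name}.bwd", c_in, units, rng)

    def params(self) -> list[Parameter]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[:, ::-1], train)[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        u = self.units
        dxf = self.fwd.backward(grad[:, :, :u])
        dxb = self.bwd.backward(grad[:, ::-1, u:])[:, ::-1]
        return dxf + dxb
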