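"""Minimal neural-network core for the sequence models in this package.

Implements exactly the building blocks the pipelines need — dense layers,
(bidirectional) LSTM layers with optional recurrent dropout, a repeat-vector
adapter for sequence autoencoders, MSE loss and the Adam optimizer — in pure
numpy with hand-derived backpropagation.  Everything is float64 and driven
by an explicit :class:`numpy.random.Generator`, so training is bit-for-bit
reproducible for a given seed on a given platform.

The scope is deliberately narrow: small models (tens of thousands of
parameters) trained on CPU-sized window datasets.  Gradients are verified
against finite differences in the test suite.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .errors import ParameterError

# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_ACT = {
    "linear": (lambda x: x, lambda x, a: np.ones_like(a)),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x, a: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x, a: 1.0 - a * a),
    "sigmoid": (_sigmoid, lambda x, a: a * (1.0 - a)),
}


def _act(name: str):
    try:
        return _ACT[name]
    except KeyError:
        raise ParameterError(f"unknown activation {name!r}") from None


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    """Interface: forward caches what backward needs; params/grads align."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    """Fully connected layer ``y = act(x W + b)``.

    Accepts input of shape (..., n_in) and applies the affine map to the
    last axis, so the same layer serves as a time-distributed head on
    (B, L, n_in) sequences.
    """

    def __init__(self, n_in: int, n_out: int, activation: str = "linear", *, rng):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self._f, self._df = _act(activation)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._shape = x.shape
        self._x = x.reshape(-1, x.shape[-1])
        self._z = self._x @ self.W + self.b
        self._a = self._f(self._z)
        return self._a.reshape(*x.shape[:-1], self.W.shape[1])

    def backward(self, grad):
        g = grad.reshape(-1, grad.shape[-1]) * self._df(self._z, self._a)
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return (g @ self.W.T).reshape(self._shape)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class LSTM(Layer):
    """Single-direction LSTM over (B, L, n_in) sequences.

    Gate order i, f, g, o.  ``activation`` applies to the cell candidate and
    the cell output (Keras convention); gates are always sigmoid.  Recurrent
    dropout draws one mask per sequence (applied to h_{t-1} in the gate
    input) during training.  Forget-gate bias initialized to 1.
    """

    def __init__(
        self,
        n_in: int,
        n_units: int,
        *,
        return_sequences: bool = True,
        activation: str = "tanh",
        recurrent_dropout: float = 0.0,
        rng,
    ):
        H = n_units
        lim_x = np.sqrt(6.0 / (n_in + 4 * H))
        lim_h = np.sqrt(6.0 / (H + 4 * H))
        self.Wx = rng.uniform(-lim_x, lim_x, size=(n_in, 4 * H))
        self.Wh = rng.uniform(-lim_h, lim_h, size=(H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0
        self.H = H
        self.return_sequences = return_sequences
        self.activation = activation
        self._f, self._df = _act(activation)
        self.recurrent_dropout = recurrent_dropout
        self._rng = rng
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        B, L, _ = x.shape
        H = self.H
        p = self.recurrent_dropout
        if train and p > 0.0:
            mask = (self._rng.random((B, H)) >= p) / (1.0 - p)
        else:
            mask = np.ones((B, H))
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._mask = mask
        self._cache = []
        out = np.empty((B, L, H))
        for t in range(L):
            hd = h * mask
            z = x[:, t, :] @ self.Wx + hd @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            zg = z[:, 2 * H : 3 * H]
            g = self._f(zg)
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            a = self._f(c)
            h = o * a
            out[:, t, :] = h
            self._cache.append((hd, c_prev, i, f, zg, g, o, c, a))
        return out if self.return_sequences else out[:, -1, :]

    def backward(self, grad):
        x, mask = self._x, self._mask
        B, L, _ = x.shape
        H = self.H
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(L - 1, -1, -1):
            hd, c_prev, i, f, zg, g, o, c, a = self._cache[t]
            if self.return_sequences:
                dh = grad[:, t, :] + dh_next
            else:
                dh = dh_next + (grad if t == L - 1 else 0.0)
            do = dh * a
            dc = dc_next + dh * o * self._df(c, a)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * self._df(zg, g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dWx += x[:, t, :].T @ dz
            self.dWh += hd.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh_next = (dz @ self.Wh.T) * mask
        return dx

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]


class Bidirectional(Layer):
    """Two LSTMs over opposite time directions, outputs concatenated.

    With ``return_sequences`` the output is (B, L, 2H) with the backward
    pass time-realigned; without, it is (B, 2H) from each direction's final
    state.
    """

    def __init__(self, n_in: int, n_units: int, *, return_sequences=True, **kw):
        self.fwd = LSTM(n_in, n_units, return_sequences=return_sequences, **kw)
        self.bwd = LSTM(n_in, n_units, return_sequences=return_sequences, **kw)
        self.return_sequences = return_sequences

    def forward(self, x, train=False):
        yf = self.fwd.forward(x, train)
        yb = self.bwd.forward(x[:, ::-1, :], train)
        if self.return_sequences:
            return np.concatenate([yf, yb[:, ::-1, :]], axis=2)
        return np.concatenate([yf, yb], axis=1)

    def backward(self, grad):
        H = self.fwd.H
        if self.return_sequences:
            dxf = self.fwd.backward(grad[:, :, :H])
            dxb = self.bwd.backward(grad[:, ::-1, H:])
        else:
            dxf = self.fwd.backward(grad[:, :H])
            dxb = self.bwd.backward(grad[:, H:])
        return dxf + dxb[:, ::-1, :]

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def grads(self):
        return self.fwd.grads() + self.bwd.grads()


class RepeatVector(Layer):
    """Tile a (B, H) state into a (B, L, H) sequence (autoencoder bridge)."""

    def __init__(self, L: int):
        self.L = L

    def forward(self, x, train=False):
        return np.repeat(x[:, None, :], self.L, axis=1)

    def backward(self, grad):
        return grad.sum(axis=1)


# ---------------------------------------------------------------------------
# model container, loss, optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    """A stack of layers trained with MSE loss and Adam."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def predict(self, x, batch_size: int = 256):
        outs = [
            self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs) if outs else np.empty((0,))

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int,
        batch_size: int,
        rng: np.random.Generator,
        lr: float = 1e-3,
        clipnorm: float = 5.0,
        verbose: bool = False,
    ) -> list[float]:
        """Mini-batch training with MSE loss; returns per-epoch mean loss."""
        if len(x) == 0:
            raise ParameterError("cannot fit on an empty dataset")
        opt = Adam(self.params(), lr=lr)
        history: list[float] = []
        n = len(x)
        for epoch in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                pred = self.forward(xb, train=True)
                diff = pred - yb
                total += float(np.mean(diff * diff)) * len(idx)
                self.backward(2.0 * diff / diff.size)
                grads = self.grads()
                if clipnorm is not None:
                    gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                    if gnorm > clipnorm:
                        scale = clipnorm / gnorm
                        grads = [g * scale for g in grads]
                opt.step(grads)
            history.append(total / n)
            if verbose and (epoch % 20 == 0 or epoch == epochs - 1):
                print(f"epoch {epoch + 1}/{epochs}: mse {history[-1]:.6f}")
        return history

    # -- weight (de)serialization -------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ParameterError(
                f"{len(weights)} weight arrays for {len(params)} parameters"
            )
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ParameterError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    diff = np.asarray(pred) - np.asarray(target)
    return float(np.mean(diff * diff))
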