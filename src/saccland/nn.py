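"""Minimal NumPy neural-network core: LSTM / simple-RNN layers with
backprop-through-time, dense heads, softmax cross-entropy, and Adam.

This module exists because the sequence models are the heart of the method;
they are small (tens of thousands of parameters) and train comfortably on a
CPU with vectorised NumPy.  Gate layout follows the common i, f, g, o order
with a forget-gate bias of 1.  All randomness flows through an explicit
``numpy.random.Generator`` so training is reproducible bit-for-bit for a
fixed seed and dtype.

Shapes: sequence inputs are ``(batch, time, features)``; recurrent layers
return the full hidden sequence ``(batch, time, hidden)`` so layers stack.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = [
    "Dense",
    "LSTMLayer",
    "SimpleRNNLayer",
    "SequenceNet",
    "MLP",
    "Adam",
    "softmax",
]


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(rng: np.random.Generator, rows: int, cols: int, dtype) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return q[:rows, :cols].astype(dtype)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


class Dense:
    """Affine layer ``y = x W + b`` (activation applied by the caller)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out), dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [(self, "W"), (self, "b")]

    def grads(self):
        return [self.dW, self.db]


class LSTMLayer:
    """Single LSTM layer over a full sequence, with BPTT.

    Parameter count is ``4 ((I + H) H + H)`` — input kernel, recurrent
    kernel and bias for the four gates.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        H = n_hidden
        self.n_in, self.n_hidden = n_in, H
        self.Wx = glorot_uniform(rng, n_in, 4 * H, (n_in, 4 * H), dtype)
        self.Wh = np.concatenate(
            [orthogonal(rng, H, H, dtype) for _ in range(4)], axis=1
        )
        self.b = np.zeros(4 * H, dtype=dtype)
        self.b[H:2 * H] = 1.0  # forget-gate bias

    @property
    def n_params(self) -> int:
        return self.Wx.size + self.Wh.size + self.b.size

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        H = self.n_hidden
        dtype = self.Wx.dtype
        h = np.zeros((B, H), dtype=dtype)
        c = np.zeros((B, H), dtype=dtype)
        gates = np.empty((T, B, 4 * H), dtype=dtype)
        cs = np.empty((T, B, H), dtype=dtype)       # c_t
        tanh_cs = np.empty((T, B, H), dtype=dtype)
        hs = np.empty((B, T, H), dtype=dtype)
        xW = (X.reshape(B * T, -1) @ self.Wx + self.b).reshape(B, T, 4 * H)
        for t in range(T):
            z = gates[t]
            np.add(xW[:, t], h @ self.Wh, out=z)
            _sigmoid(z[:, :H], out=z[:, :H])
            _sigmoid(z[:, H:2 * H], out=z[:, H:2 * H])
            np.tanh(z[:, 2 * H:3 * H], out=z[:, 2 * H:3 * H])
            _sigmoid(z[:, 3 * H:], out=z[:, 3 * H:])
            c = z[:, H:2 * H] * c
            c += z[:, :H] * z[:, 2 * H:3 * H]
            tc = np.tanh(c, out=tanh_cs[t])
            h = hs[:, t]
            np.multiply(z[:, 3 * H:], tc, out=h)
            cs[t] = c
        self._cache = (X, gates, cs, tanh_cs, hs)
        return hs

    def backward(self, dH: np.ndarray) -> np.ndarray:
        """``dH``: gradient w.r.t. the full hidden sequence (B, T, H)."""
        X, gates, cs, tanh_cs, hs = self._cache
        B, T, _ = X.shape
        H = self.n_hidden
        dtype = self.Wx.dtype
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty_like(X)
        dh = np.zeros((B, H), dtype=dtype)      # dh_carry accumulator
        dc = np.zeros((B, H), dtype=dtype)
        dZ = np.empty((B, 4 * H), dtype=dtype)
        tmp = np.empty((B, H), dtype=dtype)
        zeros = np.zeros((B, H), dtype=dtype)
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H:2 * H]
            g = gates[t, :, 2 * H:3 * H]
            o = gates[t, :, 3 * H:]
            tc = tanh_cs[t]
            c_prev = cs[t - 1] if t > 0 else zeros
            h_prev = hs[:, t - 1] if t > 0 else zeros
            dh += dH[:, t]
            # dc += dh * o * (1 - tc^2);  do = dh * tc
            np.multiply(dh, o, out=tmp)
            dc += tmp
            tmp *= tc * tc
            dc -= tmp
            np.multiply(dh, tc, out=dZ[:, 3 * H:])
            dZ[:, 3 * H:] *= o * (1.0 - o)
            np.multiply(dc, g, out=dZ[:, :H])
            dZ[:, :H] *= i * (1.0 - i)
            np.multiply(dc, c_prev, out=dZ[:, H:2 * H])
            dZ[:, H:2 * H] *= f * (1.0 - f)
            np.multiply(dc, i, out=dZ[:, 2 * H:3 * H])
            dZ[:, 2 * H:3 * H] *= 1.0 - g * g
            dWx += X[:, t].T @ dZ
            dWh += h_prev.T @ dZ
            db += dZ.sum(axis=0)
            dX[:, t] = dZ @ self.Wx.T
            np.matmul(dZ, self.Wh.T, out=dh)
            dc *= f
        self.dWx, self.dWh, self.db = dWx, dWh, db
        return dX

    def params(self):
        return [(self, "Wx"), (self, "Wh"), (self, "b")]

    def grads(self):
        return [self.dWx, self.dWh, self.db]


class SimpleRNNLayer:
    """Plain tanh recurrent layer: ``h_t = tanh(x_t Wx + h_{t-1} Wh + b)``."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        H = n_hidden
        self.n_in, self.n_hidden = n_in, H
        self.Wx = glorot_uniform(rng, n_in, H, (n_in, H), dtype)
        self.Wh = orthogonal(rng, H, H, dtype)
        self.b = np.zeros(H, dtype=dtype)

    @property
    def n_params(self) -> int:
        return self.Wx.size + self.Wh.size + self.b.size

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        H = self.n_hidden
        h = np.zeros((B, H), dtype=self.Wx.dtype)
        hs = np.empty((B, T, H), dtype=self.Wx.dtype)
        for t in range(T):
            h = np.tanh(X[:, t] @ self.Wx + h @ self.Wh + self.b)
            hs[:, t] = h
        self._cache = (X, hs)
        return hs

    def backward(self, dH: np.ndarray) -> np.ndarray:
        X, hs = self._cache
        B, T, _ = X.shape
        H = self.n_hidden
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty_like(X)
        dh_carry = np.zeros((B, H), dtype=X.dtype)
        for t in range(T - 1, -1, -1):
            h = hs[:, t]
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=X.dtype)
            dz = (dH[:, t] + dh_carry) * (1.0 - h * h)
            dWx += X[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.Wx.T
            dh_carry = dz @ self.Wh.T
        self.dWx, self.dWh, self.db = dWx, dWh, db
        return dX

    def params(self):
        return [(self, "Wx"), (self, "Wh"), (self, "b")]

    def grads(self):
        return [self.dWx, self.dWh, self.db]


class Adam:
    """Adam optimizer over the (object, attribute-name) parameter handles."""

    def __init__(self, handles, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.handles = list(handles)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, n)) for o, n in self.handles]
        self.v = [np.zeros_like(getattr(o, n)) for o, n in self.handles]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, ((obj, name), g) in enumerate(zip(self.handles, grads)):
            p = getattr(obj, name)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class SequenceNet:
    """Two stacked recurrent layers with a linear regression head and/or a
    softmax classification head on the final hidden state.

    ``loss`` selects the training objective: ``"l1"`` squared-Euclidean
    regression, ``"l2"`` categorical cross-entropy on the discretized target,
    ``"l3"`` their combination ``L1 + beta * L2``.
    """

    def __init__(self, n_in: int, hidden: tuple[int, int], *,
                 reg_units: int | None, cls_units: int | None,
                 loss: str = "l1", beta: float = 0.7,
                 cell: str = "lstm", seed: int = 0, dtype=np.float32):
        if loss not in ("l1", "l2", "l3"):
            raise ValueError(f"unknown loss {loss!r}")
        if loss in ("l1", "l3") and reg_units is None:
            raise ValueError("regression head required for L1/L3")
        if loss in ("l2", "l3") and cls_units is None:
            raise ValueError("classification head required for L2/L3")
        rng = np.random.default_rng(seed)
        Layer = LSTMLayer if cell == "lstm" else SimpleRNNLayer
        self.layers = [
            Layer(n_in, hidden[0], rng, dtype),
            Layer(hidden[0], hidden[1], rng, dtype),
        ]
        top = hidden[1]
        self.reg_head = Dense(top, reg_units, rng, dtype) if reg_units else None
        self.cls_head = Dense(top, cls_units, rng, dtype) if cls_units else None
        self.loss_name = loss
        self.beta = beta
        self.dtype = dtype

    @property
    def n_params(self) -> int:
        n = sum(l.n_params for l in self.layers)
        if self.loss_name in ("l1", "l3") and self.reg_head is not None:
            n += self.reg_head.n_params
        if self.loss_name in ("l2", "l3") and self.cls_head is not None:
            n += self.cls_head.n_params
        return n

    def _all_param_handles(self):
        handles = []
        for l in self.layers:
            handles += l.params()
        if self.reg_head is not None:
            handles += self.reg_head.params()
        if self.cls_head is not None:
            handles += self.cls_head.params()
        return handles

    def _all_grads(self):
        grads = []
        for l in self.layers:
            grads += l.grads()
        if self.reg_head is not None:
            grads += self.reg_head.grads()
        if self.cls_head is not None:
            grads += self.cls_head.grads()
        return grads

    def forward(self, X: np.ndarray):
        """Returns ``(regression output or None, class probabilities or None)``."""
        h = np.asarray(X, dtype=self.dtype)
        for layer in self.layers:
            h = layer.forward(h)
        h_last = h[:, -1]
        self._h_shape = h.shape
        pred = self.reg_head.forward(h_last) if self.reg_head is not None else None
        probs = None
        if self.cls_head is not None:
            self._logits = self.cls_head.forward(h_last)
            probs = softmax(self._logits)
            self._probs = probs
        return pred, probs

    def loss_and_grads(self, X: np.ndarray, T_reg: np.ndarray | None,
                       T_cls: np.ndarray | None):
        """One forward/backward pass; returns (total, l1 component, l2
        component) as batch means and leaves gradients on the layers."""
        B = X.shape[0]
        pred, probs = self.forward(X)
        l1 = l2 = 0.0
        dh_last = np.zeros((B, self._h_shape[2]), dtype=self.dtype)
        if self.loss_name in ("l1", "l3"):
            diff = pred - T_reg.astype(self.dtype)
            l1 = float(np.mean(np.sum(diff * diff, axis=1)))
            dh_last += self.reg_head.backward(2.0 * diff / B)
        if self.loss_name in ("l2", "l3"):
            idx = np.arange(B)
            p_true = np.clip(probs[idx, T_cls], 1e-12, None)
            l2 = float(np.mean(-np.log(p_true)))
            dlogits = probs.copy()
            dlogits[idx, T_cls] -= 1.0
            w = 1.0 if self.loss_name == "l2" else self.beta
            dh_last += self.cls_head.backward(w * dlogits / B)
        dH = np.zeros(self._h_shape, dtype=self.dtype)
        dH[:, -1] = dh_last
        for layer in reversed(self.layers):
            dH = layer.backward(dH)
        if self.loss_name == "l1":
            total = l1
        elif self.loss_name == "l2":
            total = l2
        else:
            total = l1 + self.beta * l2
        return total, l1, l2

    def fit(self, X: np.ndarray, T_reg: np.ndarray | None,
            T_cls: np.ndarray | None, *, epochs: int = 60,
            batch_size: int = 256, lr: float = 1e-3,
            seed: int = 0) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean loss."""
        n = X.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        opt = Adam(self._all_param_handles(), lr=lr)
        rng = np.random.default_rng(seed)
        history: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                sel = order[start:start + batch_size]
                loss, _, _ = self.loss_and_grads(
                    X[sel],
                    None if T_reg is None else T_reg[sel],
                    None if T_cls is None else T_cls[sel],
                )
                opt.step(self._all_grads())
                total += loss * len(sel)
            history.append(total / n)
        return history

    def predict(self, X: np.ndarray):
        return self.forward(X)


class MLP:
    """Feed-forward net on flattened coordinate sequences: two ReLU hidden
    layers and a linear output, trained with squared-error loss."""

    def __init__(self, n_in: int, hidden: tuple[int, int] = (32, 32),
                 n_out: int = 2, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.l1 = Dense(n_in, hidden[0], rng, dtype)
        self.l2 = Dense(hidden[0], hidden[1], rng, dtype)
        self.l3 = Dense(hidden[1], n_out, rng, dtype)
        self.dtype = dtype

    @property
    def n_params(self) -> int:
        return self.l1.n_params + self.l2.n_params + self.l3.n_params

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype).reshape(X.shape[0], -1)
        a1 = np.maximum(self.l1.forward(X), 0.0)
        self._a1 = a1
        a2 = np.maximum(self.l2.forward(a1), 0.0)
        self._a2 = a2
        return self.l3.forward(a2)

    def loss_and_grads(self, X: np.ndarray, T: np.ndarray) -> float:
        B = X.shape[0]
        pred = self.forward(X)
        diff = pred - T.astype(self.dtype)
        loss = float(np.mean(np.sum(diff * diff, axis=1)))
        d = self.l3.backward(2.0 * diff / B)
        d = self.l2.backward(d * (self._a2 > 0))
        self.l1.backward(d * (self._a1 > 0))
        return loss

    def fit(self, X: np.ndarray, T: np.ndarray, *, epochs: int = 60,
            batch_size: int = 256, lr: float = 1e-3, seed: int = 0) -> list[float]:
        n = X.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        handles = self.l1.params() + self.l2.params() + self.l3.params()
        opt = Adam(handles, lr=lr)
        rng = np.random.default_rng(seed)
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                sel = order[start:start + batch_size]
                loss = self.loss_and_grads(X[sel], T[sel])
                opt.step(self.l1.grads() + self.l2.grads() + self.l3.grads())
                total += loss * len(sel)
            history.append(total / n)
        return history

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)
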