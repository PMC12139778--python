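"""Minimal seeded 1-D convolutional network engine (numpy).

Forward/backward passes for Conv1d -> ReLU -> MaxPool blocks followed by
dense layers, trained with Adam on class-weighted cross-entropy. Small
by design: inputs are single-channel fluorescence traces (length ~1000)
and networks have at most a few hundred thousand parameters, so CPU
matmuls via im2col are fast enough and fully deterministic given a seed.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Network"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L) -> (B, L, C*k) windows with zero 'same' padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, k, axis=2)      # (B, C, L, k)
    b, c, l, _ = win.shape
    return win.transpose(0, 2, 1, 3).reshape(b, l, c * k)


class _Conv1d:
    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.w = rng.normal(0, scale, size=(c_in * k, c_out))
        self.b = np.zeros(c_out)
        self.k, self.c_in = k, c_in

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = _im2col(x, self.k)           # (B, L, C*k)
        out = self._cols @ self.w + self.b        # (B, L, C_out)
        return out.transpose(0, 2, 1)             # (B, C_out, L)

    def backward(self, grad: np.ndarray):
        g = grad.transpose(0, 2, 1)               # (B, L, C_out)
        b, l, _ = g.shape
        self.gw = self._cols.reshape(b * l, -1).T @ g.reshape(b * l, -1)
        self.gb = g.sum(axis=(0, 1))
        gcols = g @ self.w.T                      # (B, L, C*k)
        # scatter windows back (col2im)
        pad = self.k // 2
        gx = np.zeros((b, self.c_in, l + 2 * pad))
        gcols = gcols.reshape(b, l, self.c_in, self.k)
        for j in range(self.k):
            gx[:, :, j:j + l] += gcols[:, :, :, j].transpose(0, 2, 1)
        return gx[:, :, pad:pad + l]

    @property
    def grads(self):
        return [self.gw, self.gb]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class _MaxPool:
    params: list = []
    grads: list = []

    def __init__(self, size: int):
        self.size = size

    def forward(self, x):
        b, c, l = x.shape
        l_out = l // self.size
        self._in_len = l
        xr = x[:, :, : l_out * self.size].reshape(b, c, l_out, self.size)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, grad):
        b, c, l_out = grad.shape
        gx = np.zeros((b, c, l_out, self.size))
        bi, ci, li = np.ogrid[:b, :c, :l_out]
        gx[bi, ci, li, self._arg] = grad
        gx = gx.reshape(b, c, l_out * self.size)
        if gx.shape[2] < self._in_len:
            gx = np.pad(gx, ((0, 0), (0, 0), (0, self._in_len - gx.shape[2])))
        return gx


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    @property
    def grads(self):
        return [self.gw, self.gb]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """Conv blocks + dense head; weighted softmax cross-entropy; Adam."""

    def __init__(self, input_length: int, conv_blocks, pool_size: int,
                 dense_layers, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_length = input_length
        self.layers: list = []
        c, l = 1, input_length
        for kernel, filters in conv_blocks:
            self.layers += [_Conv1d(c, filters, kernel, rng), _ReLU(),
                            _MaxPool(pool_size)]
            c, l = filters, l // pool_size
        self.layers.append(_Flatten())
        n = c * l
        for width in dense_layers:
            self.layers += [_Dense(n, width, rng), _ReLU()]
            n = width
        self.layers.append(_Dense(n, n_classes, rng))
        self.n_classes = n_classes
        self._adam_m = [np.zeros_like(p) for lay in self.layers
                        for p in lay.params]
        self._adam_v = [np.zeros_like(p) for lay in self.layers
                        for p in lay.params]
        self._adam_t = 0

    @property
    def n_params(self) -> int:
        return sum(p.size for lay in self.layers for p in lay.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, L) -> logits (B, n_classes)."""
        h = x[:, None, :]
        for lay in self.layers:
            h = lay.forward(h)
        return h

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for a in range(0, len(x), batch_size):
            out.append(_softmax(self.forward(x[a:a + batch_size])))
        return np.concatenate(out) if out else np.empty((0, self.n_classes))

    def _step(self, x, y, class_weights, lr, beta1=0.9, beta2=0.999,
              eps=1e-8) -> float:
        logits = self.forward(x)
        probs = _softmax(logits)
        w = class_weights[y]
        loss = float(np.mean(-w * np.log(probs[np.arange(len(y)), y] + 1e-12)))
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        grad = probs.copy()
        grad[np.arange(len(y)), y] -= 1.0
        grad *= w[:, None] / len(y)
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        # Adam update
        self._adam_t += 1
        i = 0
        for lay in self.layers:
            for p, g in zip(lay.params, lay.grads):
                self._adam_m[i] = beta1 * self._adam_m[i] + (1 - beta1) * g
                self._adam_v[i] = beta2 * self._adam_v[i] + (1 - beta2) * g * g
                mhat = self._adam_m[i] / (1 - beta1 ** self._adam_t)
                vhat = self._adam_v[i] / (1 - beta2 ** self._adam_t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
                i += 1
        return loss

    def fit(self, x: np.ndarray, y: np.ndarray, class_weights: np.ndarray,
            lr: float, batch_size: int, epochs: int, seed: int = 0) -> list:
        """Seeded minibatch training; returns the per-epoch mean loss."""
        rng = np.random.default_rng(seed)
        history = []
        for _ in range(epochs):
            order = rng.permutation(len(x))
            losses = []
            for a in range(0, len(x), batch_size):
                idx = order[a:a + batch_size]
                losses.append(self._step(x[idx], y[idx], class_weights, lr))
            history.append(float(np.mean(losses)))
        return history

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict:
        return {f"p{i}": p for i, p in enumerate(
            p for lay in self.layers for p in lay.params)}

    def load_state(self, state: dict) -> None:
        flat = [p for lay in self.layers for p in lay.params]
        for i, p in enumerate(flat):
            p[...] = state[f"p{i}"]
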