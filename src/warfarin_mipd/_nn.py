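"""Small fully connected networks with Adam, in plain numpy.

Only what the two learned agents need: ReLU hidden layers, a linear or
scaled-sigmoid head, mean-squared-error loss and the Adam update.  Weights
use He initialisation; everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np


class MLP:
    def __init__(self, widths, head: str = "linear", head_scale: float = 1.0,
                 rng=None):
        """``widths``: (n_in, hidden..., n_out).  ``head``: linear|sigmoid."""
        rng = np.random.default_rng(rng)
        self.widths = tuple(int(w) for w in widths)
        self.head = head
        self.head_scale = float(head_scale)
        self.W, self.b = [], []
        for n_in, n_out in zip(self.widths[:-1], self.widths[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / n_in),
                                     size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))

    @property
    def params(self):
        return self.W + self.b

    def copy_from(self, other: "MLP") -> None:
        for dst, src in zip(self.params, other.params):
            dst[...] = src

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        h = np.atleast_2d(np.asarray(x, dtype=float))
        if cache is not None:
            cache.append(h)
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last:
                h = np.maximum(h, 0.0)
            elif self.head == "sigmoid":
                h = self.head_scale / (1.0 + np.exp(-h))
            if cache is not None:
                cache.append(h)
        return h

    def backward(self, cache, grad_out: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(output)."""
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        g = np.asarray(grad_out, dtype=float)
        if self.head == "sigmoid":
            y = cache[-1] / self.head_scale
            g = g * self.head_scale * y * (1.0 - y)
        for i in reversed(range(len(self.W))):
            h_in = cache[i]
            if i < len(self.W) - 1:
                g = g * (cache[i + 1] > 0)
            grads_W[i] = h_in.T @ g
            grads_b[i] = g.sum(axis=0)
            if i > 0:
                g = g @ self.W[i].T
        return grads_W + grads_b


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
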