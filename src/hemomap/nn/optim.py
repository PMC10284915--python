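"""AdaBelief optimizer.

Adam-like, but the second-moment accumulator tracks the variance of the
gradient around its EMA prediction ("belief" in the gradient direction),
which stabilizes small-batch training.  Defaults follow the training recipe
used throughout this package: lr 5e-5, eps 1e-12.
"""

from __future__ import annotations

import numpy as np

from .layers import Param


class AdaBelief:
    def __init__(self, params: list[Param], lr: float = 5e-5,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-12):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._s = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, s in zip(self.params, self._m, self._s):
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            diff = g - m
            s += (1.0 - self.b2) * (diff * diff - s) + self.eps
            m_hat = m / bc1
            s_hat = s / bc2
            p.value -= (self.lr * m_hat / (np.sqrt(s_hat) + self.eps)).astype(
                p.value.dtype)


class SGD:
    """Plain momentum SGD; configurable fallback optimizer."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v += p.grad
            p.value -= (self.lr * v).astype(p.value.dtype)
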