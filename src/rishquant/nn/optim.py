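"""Adam optimizer over the flat layer/parameter structure."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        layers: list[Layer],
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.layers = [lay for lay in layers if lay.params]
        self.lr = learning_rate
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [
            {k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers
        ]
        self._v = [
            {k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for lay, m, v in zip(self.layers, self._m, self._v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                mhat = m[k] / bc1
                vhat = v[k] / bc2
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
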