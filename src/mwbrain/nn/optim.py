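"""Adam optimizer over (layer, parameter-name) handles."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Adam"]


class Adam:
    def __init__(self, handles: list[tuple[Layer, str]], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.handles = list(handles)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(layer.params[name]) for layer, name in self.handles]
        self._v = [np.zeros_like(layer.params[name]) for layer, name in self.handles]

    def zero_grad(self) -> None:
        for layer, _ in self.handles:
            layer.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / b1t
            vhat = self._v[i] / b2t
            p = layer.params[name]
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
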