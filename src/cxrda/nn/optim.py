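"""Adam optimizer operating on the (layer, name) parameter lists of Sequential."""

from __future__ import annotations

import numpy as np

from .layers import Sequential


class Adam:
    """Adaptive moment estimation. One instance per network component so the
    per-loss update partition of the adaptation schemes stays explicit."""

    def __init__(self, model: Sequential, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._slots = model.trainable_params()
        self._m = [np.zeros_like(layer.params[name]) for layer, name in self._slots]
        self._v = [np.zeros_like(layer.params[name]) for layer, name in self._slots]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for i, (layer, name) in enumerate(self._slots):
            g = layer.grads[name]
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / bc1
            vhat = self._v[i] / bc2
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.params[name].dtype
            )

    def zero_grads(self) -> None:
        self.model.zero_grads()
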