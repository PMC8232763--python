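"""Adam optimizer over a model's parameter dictionaries."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adaptive-moment gradient descent (bias-corrected first/second moments).

    Default learning rate 1e-4 matches the pipeline's training configuration.
    """

    def __init__(self, model, lr: float = 1e-4, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.model = model
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {name: np.zeros_like(v) for name, _, _, v in model.named_parameters()}
        self.v = {name: np.zeros_like(v) for name, _, _, v in model.named_parameters()}

    def step(self) -> None:
        """Apply one update from the gradients accumulated in the layers."""
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, layer, key, val in self.model.named_parameters():
            g = layer.grads[key]
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / bc1
            vhat = self.v[name] / bc2
            layer.params[key] = val - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        self.model.zero_grad()
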