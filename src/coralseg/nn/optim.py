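"""Adam optimizer and the exponential per-epoch learning-rate decay."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter

__all__ = ["Adam", "lr_at_epoch"]


def lr_at_epoch(v0: float, alpha: float, epoch: int) -> float:
    """Exponentially decayed rate ``alpha**j * v0`` at 0-based epoch j.

    Epoch 0 uses exactly the initial rate v0; consecutive epochs differ
    by the constant factor alpha.
    """
    if v0 <= 0:
        raise ValueError("initial learning rate must be positive")
    if not 0 < alpha <= 1:
        raise ValueError("decay coefficient must lie in (0, 1]")
    if epoch < 0:
        raise ValueError("epoch index must be non-negative")
    return (alpha ** epoch) * v0


class Adam:
    """Adam with bias-corrected first/second moments (b1=0.9, b2=0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
            p.data -= update.astype(p.data.dtype)
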