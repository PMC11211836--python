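"""Optimizers: rectified Adam (default) and plain Adam fallback.

RAdam rectifies the variance of the adaptive learning rate in early steps,
removing the need for warmup; when the rectification term is undefined
(small step count) the update falls back to momentum SGD as in the original
formulation.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class RAdam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        rectify: bool = True,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.rectify = rectify
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1t, b2t = self.b1**t, self.b2**t
        if self.rectify:
            rho = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            m_hat = m / (1.0 - b1t)
            if not self.rectify:
                v_hat = v / (1.0 - b2t)
                p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            elif rho > 4.0:
                v_hat = np.sqrt(v / (1.0 - b2t))
                r = np.sqrt(
                    ((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho)
                )
                p.data -= self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p.data -= self.lr * m_hat


def make_optimizer(params: list[Tensor], lr: float, use_radam: bool = True) -> RAdam:
    return RAdam(params, lr=lr, rectify=use_radam)
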