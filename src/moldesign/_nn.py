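"""Parameter initialisation and the Adam optimizer used for generator training."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, parameter

__all__ = ["glorot", "lstm_params", "Adam"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


def lstm_params(rng: np.random.Generator, input_dim: int, hidden_dim: int):
    """Packed [i, f, g, o] LSTM weights with forget-gate bias of 1."""
    wx = glorot(rng, input_dim, 4 * hidden_dim)
    wh = glorot(rng, hidden_dim, 4 * hidden_dim)
    b = np.zeros(4 * hidden_dim)
    b[hidden_dim : 2 * hidden_dim] = 1.0
    return wx, wh, parameter(b)


class Adam:
    """Adam with a stepped multiplicative learning-rate decay.

    The rate starts at ``base_lr`` and is multiplied by ``1 - decay_rate``
    every ``decay_steps`` optimizer steps.
    """

    def __init__(
        self,
        params: list[Tensor],
        base_lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        decay_rate: float = 0.03,
        decay_steps: int = 1000,
    ):
        self.params = list(params)
        self.base_lr = base_lr
        self.betas = betas
        self.eps = eps
        self.decay_rate = decay_rate
        self.decay_steps = decay_steps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    @property
    def lr(self) -> float:
        return self.base_lr * (1.0 - self.decay_rate) ** (self.t // self.decay_steps)

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        lr = self.lr
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
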