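"""Network building blocks: linear layers, shared MLPs, PointNet max-pooling,
and the AdamW optimizer."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor

__all__ = ["Linear", "MLP", "pointnet", "AdamW"]


class Linear:
    """Affine map applied to the last axis; He-initialised weights."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Parameter(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]


class MLP:
    """Stack of Linear+ReLU layers, shared across points/groups.

    ``widths`` are the hidden/output widths after the input width; the final
    layer's ReLU is optional (off for logit/regression heads).
    """

    def __init__(
        self,
        n_in: int,
        widths: list[int],
        rng: np.random.Generator,
        final_relu: bool = True,
    ):
        self.layers: list[Linear] = []
        self.final_relu = final_relu
        prev = n_in
        for w in widths:
            self.layers.append(Linear(prev, w, rng))
            prev = w
        self.n_out = prev

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_relu:
                x = x.relu()
        return x

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]


def pointnet(x: Tensor, mlp: MLP) -> Tensor:
    """Shared-MLP + max-pool over the group axis: (S, K, C) -> (S, D)."""
    return mlp(x).max(axis=1)


class AdamW:
    """Decoupled weight-decay Adam (Loshchilov & Hutter)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 0.002,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )
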