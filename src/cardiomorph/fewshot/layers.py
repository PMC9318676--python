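"""Layer and optimizer primitives on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batchnorm2d, conv2d, dropout, maxpool2d

__all__ = ["Conv2d", "BatchNorm2d", "ConvBlock", "Dropout", "Adam"]


class Conv2d:
    """3×3 same-convolution with He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3):
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        # float32 throughout the encoder: the engine is bandwidth-bound on CPU
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel))
            .astype(np.float32),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.padding = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)

    def parameters(self):
        return [self.weight, self.bias]


class BatchNorm2d:
    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running = {"mean": np.zeros(channels, dtype=np.float32),
                        "var": np.ones(channels, dtype=np.float32)}

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return batchnorm2d(x, self.gamma, self.beta, self.running, training)

    def parameters(self):
        return [self.gamma, self.beta]


class ConvBlock:
    """conv → batchnorm → ReLU → 2× max-pool."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv = Conv2d(in_ch, out_ch, rng)
        self.norm = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return maxpool2d(self.norm(self.conv(x), training).relu())

    def parameters(self):
        return self.conv.parameters() + self.norm.parameters()


class Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        return dropout(x, self.rate, rng, training)


class Adam:
    """Adam with the standard defaults; only the learning rate is tuned."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
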