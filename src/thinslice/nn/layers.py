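"""Layer/module system and the Adam optimizer for the numpy autodiff engine."""
from __future__ import annotations

import numpy as np

from .tensor import Tensor, add, conv3d, matmul, reshape


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, state dicts, callable forward."""

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv3d(Module):
    """3D convolution, kernel given per axis, stride/padding per axis.

    Kaiming-normal init scaled by ``init_scale`` (small-scale init keeps the
    residual trunk near-identity at the start of training).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 3, 3),
                 stride=(1, 1, 1), padding=(1, 1, 1), *,
                 rng: np.random.Generator, init_scale: float = 0.1):
        kernel = tuple(int(k) for k in kernel)
        fan_in = in_ch * int(np.prod(kernel))
        std = np.sqrt(2.0 / fan_in) * init_scale
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_ch, in_ch) + kernel))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))
        self.stride = tuple(int(s) for s in stride)
        self.padding = tuple(int(p) for p in padding)

    def forward(self, x: Tensor) -> Tensor:
        out = conv3d(x, self.weight, self.stride, self.padding)
        return add(out, reshape(self.bias, (1, -1, 1, 1, 1)))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, init_scale: float = 1.0):
        std = np.sqrt(2.0 / in_features) * init_scale
        self.weight = Parameter(rng.normal(0.0, std, size=(in_features,
                                                           out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), reshape(self.bias, (1, -1)))


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float(np.sum(g.astype(np.float64) ** 2))
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = np.float32(max_norm / (norm + 1e-12))
        for g in grads:
            g *= scale
    return norm


class Adam:
    """Adam with the usual bias correction."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
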