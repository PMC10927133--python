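"""Neural-network layers, parameter containers and the Adam optimizer.

Built on :mod:`radiofusion.autograd`.  Layout is NCHW throughout.  Modules
hold named :class:`Parameter` tensors and plain-ndarray buffers (batch-norm
running statistics); ``state_dict``/``load_state_dict`` give flat name->array
views used by checkpointing and by the teacher EMA update.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, concat, conv2d, maxpool2x, upsample2x

_GLOBAL_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the generator used for parameter initialization."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


def _init_rng() -> np.random.Generator:
    return _GLOBAL_RNG


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Tiny module base: attribute assignment registers children/parameters."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray):
        """Update a registered buffer in place-ish (rebinds both views)."""
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n in self._buffers:
            yield prefix + n, self._buffers[n]
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data for n, p in self.named_parameters()}
        for n, b in self.named_buffers():
            out[n] = b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own = self.state_dict()
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if strict and (missing or extra):
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} unexpected={sorted(extra)}")
        for name, p in self.named_parameters():
            if name in state:
                if p.data.shape != state[name].shape:
                    raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
                p.data = state[name].astype(np.float32).copy()
        self._load_buffers(state, "")
        return self

    def _load_buffers(self, state, prefix):
        for n in list(self._buffers):
            full = prefix + n
            if full in state:
                self._set_buffer(n, state[full].astype(self._buffers[n].dtype).copy())
        for n, m in self._modules.items():
            m._load_buffers(state, prefix + n + ".")

    def set_requires_grad(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, padding: int | None = None,
                 dilation: int = 1, groups: int = 1, bias: bool = True,
                 zero_init: bool = False):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError(f"channels ({in_ch}->{out_ch}) must be divisible by groups={groups}")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = kernel
        self.padding = dilation * (kernel - 1) // 2 if padding is None else padding
        self.dilation = dilation
        self.groups = groups
        fan_in = (in_ch // groups) * kernel * kernel
        shape = (out_ch, in_ch // groups, kernel, kernel)
        if zero_init:
            w = np.zeros(shape)
        else:
            w = _init_rng().normal(0.0, math.sqrt(2.0 / fan_in), size=shape)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        return conv2d(x, self.weight, self.bias, padding=self.padding,
                      dilation=self.dilation, groups=self.groups)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True, zero_init: bool = False):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        scale = 0.0 if zero_init else math.sqrt(2.0 / in_f)
        rng = _init_rng()
        w = rng.normal(0.0, 1.0, size=(in_f, out_f)) * scale
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.register_buffer("running_mean", np.zeros(ch, dtype=np.float32))
        self.register_buffer("running_var", np.ones(ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self._set_buffer("running_mean", ((1 - self.momentum) * self.running_mean
                                              + self.momentum * mu.data.reshape(-1)).astype(np.float32))
            self._set_buffer("running_var", ((1 - self.momentum) * self.running_var
                                             + self.momentum * var.data.reshape(-1)).astype(np.float32))
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2x(Module):
    def forward(self, x):
        return maxpool2x(x)


class Upsample2x(Module):
    def forward(self, x):
        return upsample2x(x)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C)."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    return x.max(axis=3).max(axis=2)


def avg_pool_to(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Average-pool (B,C,H,W) down to (B,C,h,w); H,W must be multiples of h,w."""
    B, C, H, W = x.shape
    h, w = out_hw
    if H == h and W == w:
        return x
    if H % h or W % w:
        raise ValueError(f"cannot average-pool {H}x{W} to {h}x{w}")
    return x.reshape(B, C, h, H // h, w, W // w).mean(axis=(3, 5))


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


__all__ = [
    "Module", "ModuleList", "Parameter", "Conv2d", "Linear", "BatchNorm2d",
    "Sequential", "ReLU", "Sigmoid", "MaxPool2x", "Upsample2x", "Adam",
    "manual_seed", "global_avg_pool", "global_max_pool", "avg_pool_to",
    "Tensor", "concat",
]
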