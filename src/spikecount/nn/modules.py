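"""Layer abstractions over the autodiff engine (Module / Conv2d / BatchNorm2d / ...)."""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
]

_init_rng = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reset the global parameter-initialization stream (determinism contract)."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal layer container with named parameters, buffers and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- mode ----------------------------------------------------------
    def train(self, flag: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", flag)
        return self

    def eval(self):
        return self.train(False)

    # -- serialization -------------------------------------------------
    def state_dict(self):
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: np.array(b, copy=True) for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d, strict=True):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = [k for k in list(own) + list(bufs) if k not in d]
        unexpected = [k for k in d if k not in own and k not in bufs]
        if strict and (missing or unexpected):
            raise KeyError(f"state mismatch: missing={missing}, unexpected={unexpected}")
        for k, v in d.items():
            if k in own:
                if own[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}")
                own[k].data = np.asarray(v, dtype=own[k].data.dtype).copy()
            elif k in bufs:
                bufs[k][...] = v
        return missing, unexpected

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, cin, cout, kernel_size, stride=1, padding=0, bias=True):
        super().__init__()
        k = int(kernel_size)
        fan_in = cin * k * k
        bound = float(np.sqrt(2.0 / fan_in))  # He initialization
        self.weight = Parameter(_init_rng.normal(0.0, bound, size=(cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride, self.padding = int(stride), int(padding)

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return F.batch_norm2d(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class Linear(Module):
    def __init__(self, cin, cout, bias=True):
        super().__init__()
        bound = float(np.sqrt(2.0 / cin))
        self.weight = Parameter(_init_rng.normal(0.0, bound, size=(cout, cin)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)
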