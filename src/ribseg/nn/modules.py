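"""Layer abstractions over the autograd primitives.

Parameters are registered by attribute name so that `named_parameters`
yields stable, hierarchical names — the ablation tests rely on strict
name-set nesting between model variants.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")
        for name, p in own.items():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.shape)
        for name, b in bufs.items():
            b[...] = state[name]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """2D convolution; padding defaults to 'same' for odd kernels at stride 1."""

    def __init__(self, cin, cout, kernel, rng, stride=1, dilation=1,
                 padding=None, bias=True):
        super().__init__()
        if padding is None:
            padding = dilation * (kernel - 1) // 2
        self.stride, self.dilation, self.padding = stride, dilation, padding
        fan_in = cin * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization
        self.weight = Tensor(
            rng.normal(0.0, scale, (cout, cin, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.dilation,
                         self.padding)


class ConvTranspose2d(Module):
    """Transposed convolution with kernel == stride (exact upsample)."""

    def __init__(self, cin, cout, stride, rng, bias=True):
        super().__init__()
        self.stride = stride
        scale = np.sqrt(2.0 / (cin * stride * stride))
        self.weight = Tensor(
            rng.normal(0.0, scale, (cin, cout, stride, stride)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x):
        return ag.conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Tensor(np.ones(channels), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float64))

    def forward(self, x):
        return ag.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                               self.running_var, self.training, self.momentum,
                               self.eps)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._order = [f"m{i}" for i in range(len(mods))]

    def forward(self, x):
        for name in self._order:
            x = self._modules[name](x)
        return x
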