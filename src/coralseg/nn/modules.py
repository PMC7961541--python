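"""Layer objects: parameter containers composing the ops in :mod:`ops`.

Initialisation is He fan-in scaled and fully determined by the
``numpy.random.Generator`` handed to each constructor, so a model built
twice from the same seed has bit-identical parameters.
"""

from __future__ import annotations

import numpy as np

from . import ops
from .autograd import Parameter, Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "ReLU",
           "MaxPool2d", "Sequential"]


class Module:
    """Base class: parameter/buffer discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, **kwargs):
        return self.forward(x, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        out = []
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                out.append(val)
        for _, child in self._children():
            out.extend(child.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                state[prefix + name] = val.data
            elif isinstance(val, np.ndarray):  # buffers (running stats)
                state[prefix + name] = val
        for name, child in self._children():
            state.update(child.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray],
                        prefix: str = "") -> None:
        for name, val in list(vars(self).items()):
            if isinstance(val, Parameter):
                val.data = np.array(state[prefix + name], dtype=val.data.dtype)
            elif isinstance(val, np.ndarray):
                setattr(self, name, np.array(state[prefix + name],
                                             dtype=val.dtype))
        for name, child in self._children():
            child.load_state_dict(state, prefix + name + ".")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, *, stride: int = 1,
                 pad: int = 0, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = cin * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std,
                                           (cout, cin, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None
        self.stride, self.pad, self.dilation = stride, pad, dilation

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv2d(x, self.weight, self.bias, stride=self.stride,
                          pad=self.pad, dilation=self.dilation)

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm2d(Module):
    def __init__(self, c: int, *, eps: float = 1e-5, momentum: float = 0.1,
                 zero_init: bool = False, dtype=np.float32):
        super().__init__()
        init = 0.0 if zero_init else 1.0
        self.gamma = Parameter(np.full(c, init, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        return ops.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                                self.running_var, training=self.training,
                                momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, fin: int, fout: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / fin)
        self.weight = Parameter(rng.normal(0.0, std, (fout, fin)).astype(dtype))
        self.bias = Parameter(np.zeros(fout, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ops.linear(x, self.weight, self.bias)

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ops.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return ops.max_pool2d(x, self.kernel, self.stride, self.pad)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
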