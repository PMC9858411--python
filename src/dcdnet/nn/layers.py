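"""Layer modules: thin stateful wrappers over `dcdnet.nn.functional`.

Weight initialisation is explicit — every constructor takes the
`numpy.random.Generator` that draws its weights, so two builds from equal
seeds are bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "ConvBNAct",
           "he_uniform", "glorot_uniform"]


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Minimal module container with named parameters/buffers and train mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, arr in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                if buf.shape != arr.shape:
                    raise ValueError(f"buffer {key}: shape {arr.shape} != {buf.shape}")
                buf[...] = arr
            else:
                p = params[key]
                if p.data.shape != arr.shape:
                    raise ValueError(f"param {key}: shape {arr.shape} != {p.data.shape}")
                p.data = arr.astype(np.float32).copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel=3, stride: int = 1,
                 padding: str = "same", groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in = (in_ch // groups) * kh * kw
        self.weight = Parameter(he_uniform(rng, (out_ch, in_ch // groups, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class ConvTranspose2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_uniform(rng, (in_ch, out_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    # running-stat momentum 0.9 (not Keras' 0.99) so inference statistics
    # converge within the short CPU-scale training runs this package targets
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training, self.momentum, self.eps)


_ACTS = {"relu": F.relu, "relu6": F.relu6, "silu": F.silu, "linear": lambda t: t}


class ConvBNAct(Module):
    """Convolution -> batch normalization -> activation, in that order."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel=3, stride: int = 1,
                 act: str = "relu", groups: int = 1, padding: str = "same"):
        super().__init__()
        self.conv = Conv2d(rng, in_ch, out_ch, kernel, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(out_ch)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        return _ACTS[self.act](self.bn(self.conv(x)))
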