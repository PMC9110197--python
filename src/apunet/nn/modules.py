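"""Layer modules over the autodiff tensors.

Initialization is Kaiming-normal (fan-in) for convolution and linear
weights, zeros for biases; every constructor takes an explicit numpy
``Generator`` so that a model is fully determined by (spec, seed).
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def named_parameters(self):
        """Yield (dotted_name, parameter) pairs, depth-first."""

        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    yield name, v
                elif isinstance(v, Module):
                    yield from walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            yield from walk(item, f"{name}.{i}.")

        yield from walk(self, "")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"__bn{i}.running_mean"].copy()
                m.running_var = state[f"__bn{i}.running_var"].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, stride: int = 1,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = kernel // 2  # "same" for odd kernels at stride 1
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel),
                                         in_ch * kernel * kernel))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, stride: int = 2,
                 output_padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.output_padding = output_padding
        self.weight = Parameter(_kaiming(rng, (in_ch, out_ch, kernel, kernel),
                                         in_ch * kernel * kernel))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.output_padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training, self.momentum,
                              self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.linear(x, self.weight, self.bias)


class MaxPool2d(Module):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return T.max_pool2d(x, self.size)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.sigmoid(x)


class Dropout(Module):
    """Inverted dropout with its own seeded stream (reseed for reproducibility)."""

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        self.p = p
        self.reseed(seed)

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return T.dropout(x, self.p, self.rng, self.training)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam(Module):
    """Adam with L2 weight decay added to the gradient (classic, not decoupled)."""

    def __init__(self, params: list[Parameter], lr: float = 0.005,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__()
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
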