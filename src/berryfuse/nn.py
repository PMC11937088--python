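"""Neural-network layers and the Adam optimizer on top of `autodiff`."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class with parameter discovery and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
        for name, child in self._children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{params[key].data.shape} vs {value.shape}")
                params[key].data = value.astype(params[key].data.dtype).copy()
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise KeyError(f"unexpected key in state dict: {key}")
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.stride, self.padding = stride, padding
        self.weight = _he_normal(rng, (out_channels, in_channels, k, k), in_channels * k * k)
        self.bias = Tensor(np.zeros(out_channels, np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseSeparableConv(Module):
    """3x3 depthwise convolution followed by a 1x1 pointwise projection."""

    def __init__(self, in_channels, out_channels, kernel_size=3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.padding = k // 2
        self.dw_weight = _he_normal(rng, (in_channels, k, k), k * k)
        self.dw_bias = Tensor(np.zeros(in_channels, np.float32), requires_grad=True)
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=True, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.depthwise_conv2d(x, self.dw_weight, self.dw_bias, padding=self.padding)
        return self.pointwise(x)


class BatchNorm2d(Module):
    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(num_features, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, np.float32)
        self.running_var = np.ones(num_features, np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, self.training,
                               momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features, out_features, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = _he_normal(rng, (in_features, out_features), in_features)
        self.bias = Tensor(np.zeros(out_features, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to the gradient."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
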