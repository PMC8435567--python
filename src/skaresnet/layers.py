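"""Neural-network layer primitives built on the autodiff tensor.

Conventions follow the common deep-learning defaults for residual
networks: convolutions carry no bias when followed by batch norm,
He-style fan-in initialization for conv/linear weights, batch-norm
eps 1e-5 with running statistics (momentum 0.1).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, max_pool2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module system: parameter traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        def walk(name, val):
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    yield from walk(f"{name}.{i}", item)

        for name, val in vars(self).items():
            yield from walk(f"{prefix}{name}", val)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        def walk(val):
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    yield from walk(item)

        yield self
        for val in vars(self).values():
            yield from walk(val)

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        """Forward; plain ndarray in -> plain ndarray out."""
        unwrap = args and isinstance(args[0], (np.ndarray, list, tuple))
        if unwrap:
            args = (Tensor(np.asarray(args[0], dtype=np.float64)),) + args[1:]
        out = self.forward(*args, **kwargs)
        if unwrap and isinstance(out, Tensor):
            return out.numpy()
        return out

    # -- state (de)serialization ----------------------------------------
    def state_arrays(self):
        """All learnable and running-stat arrays, name -> ndarray."""
        out = {name: p.data for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, (BatchNorm2d, BatchNorm1d)):
                out[f"__bn{i}.running_mean"] = m.running_mean
                out[f"__bn{i}.running_var"] = m.running_var
        return out

    def load_state_arrays(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.shape)
        for i, m in enumerate(self.modules()):
            if isinstance(m, (BatchNorm2d, BatchNorm1d)):
                m.running_mean = np.asarray(state[f"__bn{i}.running_mean"], dtype=np.float64)
                m.running_var = np.asarray(state[f"__bn{i}.running_var"], dtype=np.float64)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, groups=1,
                 bias=False, rng=None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch // groups * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding, self.groups = kernel, stride, padding, groups
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch // groups, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        out = conv2d(x, self.weight, self.stride, self.padding, self.groups)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(rng.normal(0.0, std, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class _BatchNormBase(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.num_features = num_features
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def _normalize(self, x: Tensor, axes, shape) -> Tensor:
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xn = (x - mu) / ((var + self.eps) ** 0.5)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class BatchNorm2d(_BatchNormBase):
    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (0, 2, 3), (1, self.num_features, 1, 1))


class BatchNorm1d(_BatchNormBase):
    def forward(self, x: Tensor) -> Tensor:
        return self._normalize(x, (0,), (1, self.num_features))


class MaxPool2d(Module):
    def __init__(self, kernel, stride, padding=0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m.forward(x) if isinstance(m, Module) else m(x)
        return x
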