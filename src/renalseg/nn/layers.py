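"""Layer building blocks over the autodiff primitives."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, as_tensor, conv2d

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Dropout"]


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Parameter]:
        params = [v for v in self.__dict__.values() if isinstance(v, Parameter)]
        for child in self._children():
            params.extend(child.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus non-trainable buffers, in a stable order."""
        arrays = [p.data for p in self.parameters()]
        arrays.extend(self.buffers())
        return arrays

    def buffers(self) -> list[np.ndarray]:
        bufs = [v for k, v in self.__dict__.items()
                if isinstance(v, np.ndarray) and not isinstance(v, Parameter)]
        for child in self._children():
            bufs.extend(child.buffers())
        return bufs

    def load_state_arrays(self, arrays: list[np.ndarray]):
        targets = self.parameters()
        bufs = self.buffers()
        if len(arrays) != len(targets) + len(bufs):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects "
                f"{len(targets) + len(bufs)}"
            )
        for p, a in zip(targets, arrays[: len(targets)]):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = a.astype(np.float32)
        for buf, a in zip(bufs, arrays[len(targets):]):
            buf[...] = a


class Conv2d(Module):
    """'Same'-padded stride-1 convolution with He-normal initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        fan_in = in_channels * kernel_size * kernel_size
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size,
                                  kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        gamma = self.gamma.reshape(1, -1, 1, 1)
        beta = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * gamma + beta


class Dropout(Module):
    """Inverted dropout; draws its masks from a dedicated generator."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return as_tensor(x)
        x = as_tensor(x)
        keep = (self._rng.random(x.shape) >= self.rate).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.rate))
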