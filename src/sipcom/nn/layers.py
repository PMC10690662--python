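"""Layer modules over the autodiff core: 3D convolutions, batch norm,
PReLU, residual units, and an Adam optimizer.

Parameter initialization follows the He scheme for convolutions (fan-in,
suited to rectified activations).  Every module draws its initial weights
from the generator passed at construction, so model building is fully
reproducible from a seed.
"""

from __future__ import annotations

from collections.abc import Iterator

import numpy as np

from .tensor import (
    Tensor,
    batch_norm,
    conv3d,
    conv_transpose3d,
    prelu,
)

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "PReLU",
    "Sequential",
    "ResidualUnit",
    "Adam",
]


class Module:
    """Base class: named parameters/buffers, train/eval mode, state dict."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        return arr

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self) -> "Module":
        self.training = True
        for m in self._modules.values():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._modules.values():
            m.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update(
            {"buffer:" + name: b.copy() for name, b in self.named_buffers()}
        )
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:") :]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: {p.data.shape} vs {value.shape}"
                    )
                p.data = value.astype(p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_channels * kernel**3
        self.weight = self.register_param(
            "weight", _he_init(rng, (out_channels, in_channels, kernel, kernel, kernel), fan_in)
        )
        self.bias = self.register_param("bias", np.zeros(out_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 2,
        stride: int = 2,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        fan_in = in_channels * kernel**3
        self.weight = self.register_param(
            "weight", _he_init(rng, (in_channels, out_channels, kernel, kernel, kernel), fan_in)
        )
        self.bias = self.register_param("bias", np.zeros(out_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = self.register_param("gamma", np.ones(channels, dtype=np.float32))
        self.beta = self.register_param("beta", np.zeros(channels, dtype=np.float32))
        self.running_mean = self.register_buffer(
            "running_mean", np.zeros(channels, dtype=np.float32)
        )
        self.running_var = self.register_buffer(
            "running_var", np.ones(channels, dtype=np.float32)
        )

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.alpha = self.register_param(
            "alpha", np.full(channels, init, dtype=np.float32)
        )

    def forward(self, x: Tensor) -> Tensor:
        return prelu(x, self.alpha)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ResidualUnit(Module):
    """conv-BN-PReLU-conv-BN with an additive skip, PReLU on the sum.

    A 1x1 (strided) convolution projects the skip path whenever the channel
    count or resolution changes.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.conv1 = Conv3d(in_channels, out_channels, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm3d(out_channels)
        self.act1 = PReLU(out_channels)
        self.conv2 = Conv3d(out_channels, out_channels, 3, stride=1, rng=rng)
        self.bn2 = BatchNorm3d(out_channels)
        self.act_out = PReLU(out_channels)
        self.project = None
        if stride != 1 or in_channels != out_channels:
            self.project = Conv3d(
                in_channels, out_channels, 1, stride=stride, padding=0, rng=rng
            )

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(self.act1(self.bn1(self.conv1(x)))))
        skip = self.project(x) if self.project is not None else x
        return self.act_out(y + skip)


class Adam:
    """Adam with (beta1, beta2) defaulting to the image-translation
    convention (0.5, 0.999) and a constant learning rate."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
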