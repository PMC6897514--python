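"""Layer modules over the autodiff core: convolution and batch norm.

Modules hold :class:`~posekit.nn.core.Parameter` leaves and expose them
recursively through :meth:`Module.parameters`, so optimizers and
checkpointing need no knowledge of the architecture.
"""

from __future__ import annotations

import numpy as np

from . import core
from .core import Parameter, Tensor

__all__ = ["Module", "Conv2D", "BatchNorm2D", "BnReluConv"]


class Module:
    """Base class: recursive parameter/stat discovery and train/eval mode."""

    def modules(self):
        """Yield all sub-modules depth-first, self included."""
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for mod in self.modules():
            for value in mod.__dict__.values():
                if isinstance(value, Parameter):
                    params.append(value)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and batch-norm stats."""
        out: dict[str, np.ndarray] = {}
        for i, mod in enumerate(self.modules()):
            for name, value in mod.__dict__.items():
                if isinstance(value, Parameter):
                    out[f"m{i}.{name}"] = value.data
                elif isinstance(value, np.ndarray) and name.startswith("running_"):
                    out[f"m{i}.{name}"] = value
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        current = self.state_arrays()
        if set(current) != set(state) or any(
            current[k].shape != state[k].shape for k in current
        ):
            raise ValueError("checkpoint does not match model structure")
        for key, arr in current.items():
            np.copyto(arr, state[key])


class Conv2D(Module):
    """'Same'-padded convolution, He-normal initialisation."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (kernel * kernel * cin))
        self.weight = Parameter(
            rng.normal(0.0, std, (kernel, kernel, cin, cout)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(cout, dtype=dtype))
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2D(Module):
    def __init__(self, channels: int, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        return core.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var, train
        )


class BnReluConv(Module):
    """BN -> ReLU -> Conv composite block (pre-activation ordering)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        self.bn = BatchNorm2D(cin)
        self.conv = Conv2D(cin, cout, kernel=kernel, stride=stride, rng=rng)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        return self.conv(core.relu(self.bn(x, train)))
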