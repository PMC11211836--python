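"""Network building blocks: dense layers, dilated-convolution residual
blocks with stride-2 pooling, and parameter bookkeeping."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: children and parameters are discovered by attribute scan."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32, copy=True)


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = ag.parameter(_he(rng, (n_in, n_out), n_in))
        self.b = ag.parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.w, self.b)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int, rng):
        self.w = ag.parameter(_he(rng, (c_out, c_in, kernel), c_in * kernel))
        self.b = ag.parameter(np.zeros(c_out))
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.w, self.b, self.dilation)


class TCNBlock(Module):
    """Two dilated same-length convolutions with a residual connection,
    followed by stride-2 average pooling (the down-sampling layer)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int, rng):
        self.conv1 = Conv1d(c_in, c_out, kernel, dilation, rng)
        self.conv2 = Conv1d(c_out, c_out, kernel, dilation, rng)
        self.proj = Conv1d(c_in, c_out, 1, 1, rng) if c_in != c_out else None

    def __call__(self, x: Tensor) -> Tensor:
        h = ag.relu(self.conv1(x))
        h = self.conv2(h)
        res = self.proj(x) if self.proj is not None else x
        return ag.avg_pool2(ag.relu(ag.add(h, res)))
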