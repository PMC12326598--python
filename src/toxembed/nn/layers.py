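"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor


class Module:
    """Base class with parameter discovery and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def train(self) -> "Module":
        self.training = True
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train()
        return self

    def eval(self) -> "Module":
        self.train()
        self.training = False
        for value in vars(self).values():
            if isinstance(value, Module):
                value.eval()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def visit(obj: Module, prefix: str) -> None:
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    out[key] = value.data
                elif isinstance(value, np.ndarray):
                    out[key] = value
                elif isinstance(value, Module):
                    visit(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")
                        elif isinstance(item, Parameter):
                            out[f"{key}.{i}"] = item.data

        visit(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def visit(obj: Module, prefix: str) -> None:
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    value.data = np.asarray(state[key], dtype=ag.DTYPE)
                elif isinstance(value, np.ndarray) and key in state:
                    setattr(obj, name, np.asarray(state[key]))
                elif isinstance(value, Module):
                    visit(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")
                        elif isinstance(item, Parameter):
                            item.data = np.asarray(state[f"{key}.{i}"], dtype=np.float64)

        visit(self, "")


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, init_scale: float = 0.02):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, init_scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.weight) + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gain, self.bias)


class Embedding(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator, init_scale: float = 0.02):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, init_scale, size=(n_rows, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ag.embedding(self.weight, idx)


class BatchNorm1d(Module):
    """Batch normalization over the sample axis of a (B, D) matrix.

    Training uses batch statistics (differentiated through); evaluation
    uses exponential running averages, making eval deterministic.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            # differentiate through the batch statistics via primitives:
            # column means as matmul with a 1/n vector keeps grads exact
            n = x.shape[0]
            averager = np.full((n, 1), 1.0 / n)
            col_mean = ag.swapaxes(ag.matmul(ag.swapaxes(x, 0, 1), averager), 0, 1)  # (1, D)
            centered = x - col_mean
            col_var = ag.swapaxes(
                ag.matmul(ag.swapaxes(ag.mul(centered, centered), 0, 1), averager), 0, 1
            )
            inv_std = ag.power(col_var + self.eps, -0.5)
            xhat = ag.mul(centered, inv_std)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = ag.mul(x - self.running_mean, inv)
        return ag.mul(xhat, self.gain) + self.bias
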