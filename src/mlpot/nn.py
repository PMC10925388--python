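"""Small neural-network layer toolkit on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

__all__ = ["Module", "Linear", "Embedding", "MLP", "LayerNorm"]


def _walk(value, name: str):
    """Recursively yield (name, Parameter) from attributes, incl. nested lists."""
    if isinstance(value, Parameter):
        yield name, value
    elif isinstance(value, Module):
        yield from value.named_parameters(f"{name}.")
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _walk(item, f"{name}.{i}")


class Module:
    """Base class with recursive parameter discovery and state dicts.

    Parameters and sub-modules are found by scanning instance attributes,
    in insertion order, which keeps naming deterministic.
    """

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            yield from _walk(value, f"{prefix}{name}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.requires_grad]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.astype(p.data.dtype, copy=True)

    def cast(self, dtype) -> "Module":
        for _, p in self.named_parameters():
            p.data = p.data.astype(dtype)
        return self

    def n_parameters(self, trainable_only: bool = True) -> int:
        return sum(
            p.size
            for p in self.parameters()
            if p.requires_grad or not trainable_only
        )


class Linear(Module):
    """Affine map with uniform fan-in initialization from a seeded generator."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(n_out,))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = ad.add(y, self.bias)
        return y


class Embedding(Module):
    """Lookup table mapping atomic numbers to feature vectors."""

    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 1.0, size=(n_embeddings, dim)))

    def __call__(self, index: np.ndarray) -> Tensor:
        index = np.asarray(index, dtype=np.int64)
        if np.any(index < 0) or np.any(index >= self.weight.shape[0]):
            bad = sorted(set(index[(index < 0) | (index >= self.weight.shape[0])]))
            raise ValueError(
                f"embedding index out of range (table size {self.weight.shape[0]}): {bad}"
            )
        return ad.take(self.weight, index)


class MLP(Module):
    """Linear -> SiLU -> Linear stack."""

    def __init__(self, dims: list[int], rng: np.random.Generator, bias: bool = True):
        self.layers = [
            Linear(a, b, rng, bias=bias) for a, b in zip(dims[:-1], dims[1:])
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ad.silu(x)
        return x


class LayerNorm(Module):
    """Per-atom normalization over the channel axis."""

    def __init__(self, dim: int, eps: float = 1e-8):
        self.gain = Parameter(np.ones(dim))
        self.shift = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = ad.tmean(ad.mul(centered, centered), axis=-1, keepdims=True)
        inv = ad.power(var + self.eps, -0.5)
        return ad.add(ad.mul(ad.mul(centered, inv), self.gain), self.shift)
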