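"""Reduction of per-atom features to per-sample scalar predictions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import MLP, Module

__all__ = ["OutputConfig", "OutputHead", "reduce_per_sample"]


@dataclass(frozen=True)
class OutputConfig:
    hidden_channels: int = 64
    reduce_op: str = "sum"

    def __post_init__(self):
        if self.hidden_channels < 1:
            raise ValueError("hidden_channels must be >= 1")
        if self.reduce_op not in ("sum", "mean"):
            raise ValueError("reduce_op must be 'sum' or 'mean'")


class OutputHead(Module):
    """Two-layer perceptron mapping atom features to one scalar per atom."""

    def __init__(self, in_channels: int, config: OutputConfig, rng: np.random.Generator):
        self.config = config
        self.mlp = MLP([in_channels, config.hidden_channels, 1], rng)

    def __call__(self, features: Tensor) -> Tensor:
        return self.mlp(features).reshape((-1,))


def reduce_per_sample(
    per_atom: Tensor, batch: np.ndarray, n_batches: int, reduce_op: str = "sum"
) -> Tensor:
    """Aggregate per-atom scalars over each batch segment."""
    col = per_atom.reshape((-1, 1))
    summed = ad.index_add(col, batch, n_batches).reshape((-1,))
    if reduce_op == "mean":
        counts = np.bincount(batch, minlength=n_batches).astype(np.float64)
        summed = ad.mul(summed, ad.constant(1.0 / np.maximum(counts, 1.0)))
    return summed
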