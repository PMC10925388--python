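"""Composition of representation, output head, and priors into one potential.

The assembled model implements the standard NNP contract: given atomic
numbers, positions and an optional periodic box it returns a per-sample
scalar ``y`` (the potential energy) and, when the ``derivative`` flag is on,
``neg_dy = -dy/dR`` (the atomic forces), obtained by differentiating through
the entire composition — representation, output head and priors — so the
force field is energy-conserving by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import (
    NeighborList,
    NeighborOverflowError,
    ParticleSystem,
    build_neighbors,
)
from .nn import Module
from .outputs import OutputConfig, OutputHead
from .priors import BasePrior, apply_priors
from .representations import (
    RepresentationConfig,
    build_representation,
    prepare_edges,
)

__all__ = ["AssembledModel", "Prediction", "count_parameters"]


@dataclass
class Prediction:
    """Per-sample scalar y and, if requested, per-atom neg_dy = -dy/dR."""

    y: np.ndarray  # (B,)
    neg_dy: np.ndarray | None = None  # (N, 3)


class AssembledModel(Module):
    """representation -> output head -> priors -> reduction, with autograd forces."""

    def __init__(
        self,
        representation_config: RepresentationConfig,
        output_config: OutputConfig | None = None,
        priors: list[BasePrior] | None = None,
        derivative: bool = True,
        max_num_neighbors: int = 32,
        seed: int = 0,
        precision: int = 64,
    ):
        if precision not in (32, 64):
            raise ValueError("precision must be 32 or 64")
        output_config = output_config or OutputConfig()
        rng = np.random.default_rng(seed)
        self.representation_config = representation_config
        self.output_config = output_config
        self.representation = build_representation(representation_config, rng)
        self.head = OutputHead(
            representation_config.embedding_dimension, output_config, rng
        )
        self.priors = list(priors or [])
        self.derivative = derivative
        self.max_num_neighbors = max_num_neighbors
        self.seed = seed
        self.precision = precision
        if precision == 32:
            self.cast(np.float32)

    @property
    def dtype(self):
        return np.float32 if self.precision == 32 else np.float64

    # -- core forward ---------------------------------------------------
    def forward_tensors(
        self,
        system: ParticleSystem,
        neighbors: NeighborList | None = None,
        capacity: int | None = None,
        positions: Tensor | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Differentiable forward pass; returns (y, positions tensor).

        ``capacity`` fixes the neighbor-list shape (static-shape mode);
        ``None`` sizes the list snugly to the found pairs.
        """
        if positions is None:
            positions = ad.Tensor(
                system.positions.astype(self.dtype), requires_grad=True
            )
        if neighbors is None:
            neighbors = build_neighbors(
                system,
                self.representation_config.radial.cutoff,
                capacity=capacity,
                include_transpose=True,
            )
        with ad.default_dtype(self.dtype):
            edges = prepare_edges(positions, neighbors)
            n_batches = system.n_batches
            feats = self.representation(system.atomic_numbers, edges)
            per_atom = self.head(feats.scalar)
            _, per_sample = apply_priors(
                per_atom,
                system,
                edges,
                n_batches,
                self.priors,
                self.output_config.reduce_op,
            )
        return per_sample, positions

    def predict(
        self, system: ParticleSystem, create_graph: bool = False
    ) -> Prediction:
        """Energy (and forces if the derivative flag is set) for a system."""
        if system.n_atoms == 0:
            neg = np.zeros((0, 3)) if self.derivative else None
            return Prediction(y=np.zeros(0), neg_dy=neg)
        y, positions = self.forward_tensors(system)
        if not self.derivative:
            return Prediction(y=y.data.copy())
        (gpos,) = ad.grad(
            ad.tsum(y), positions, create_graph=create_graph
        )
        return Prediction(y=y.data.copy(), neg_dy=-gpos.data)

    def predict_static(self, system: ParticleSystem, capacity: int) -> Prediction:
        """Prediction with a fixed neighbor capacity (padded, ghost-atom mode).

        Identical output to :meth:`predict` for every admissible capacity; a
        capacity below the true pair count raises
        :class:`~mlpot.geometry.NeighborOverflowError` rather than silently
        truncating.
        """
        if system.n_atoms == 0:
            neg = np.zeros((0, 3)) if self.derivative else None
            return Prediction(y=np.zeros(0), neg_dy=neg)
        y, positions = self.forward_tensors(system, capacity=capacity)
        if not self.derivative:
            return Prediction(y=y.data.copy())
        (gpos,) = ad.grad(ad.tsum(y), positions)
        return Prediction(y=y.data.copy(), neg_dy=-gpos.data)

    # -- bookkeeping ----------------------------------------------------
    def component_parameter_counts(self) -> dict[str, int]:
        counts = {
            "representation": self.representation.n_parameters(),
            "output_head": self.head.n_parameters(),
        }
        for i, prior in enumerate(self.priors):
            counts[f"prior_{i}_{type(prior).__name__}"] = prior.n_parameters()
        return counts

    def config_dict(self) -> dict:
        rc = self.representation_config
        return {
            "model": {
                "model": rc.model,
                "embedding_dimension": rc.embedding_dimension,
                "num_layers": rc.num_layers,
                "num_rbf": rc.radial.num_rbf,
                "cutoff": rc.radial.cutoff,
                "trainable_rbf": rc.radial.trainable_rbf,
                "max_z": rc.max_z,
                "vector_cutoff": rc.vector_cutoff,
                "hidden_channels": self.output_config.hidden_channels,
                "reduce_op": self.output_config.reduce_op,
                "derivative": self.derivative,
                "max_num_neighbors": self.max_num_neighbors,
                "seed": self.seed,
                "precision": self.precision,
            },
            "priors": [p.to_spec() for p in self.priors],
        }


def count_parameters(model: AssembledModel) -> int:
    """Total trainable scalar parameters (see also per-component breakdown)."""
    return sum(model.component_parameter_counts().values())
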