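"""Representation models: TensorNet-style, equivariant transformer, graph network.

All three map a particle system plus a padded neighbor list to per-atom
feature vectors.  They share the same numerical contract:

* a ghost atom (index N) is always appended internally; every padded
  neighbor slot attaches to it and is masked to an exact zero contribution,
  so increasing the list capacity never changes real atoms' features;
* edge contributions are accumulated with ``np.add.at`` on lists sorted by
  (source, target), a fixed summation order that makes the padding and
  ghost-atom guarantees bit-exact;
* scalar features are invariant under translations and the full orthogonal
  group O(3); the equivariant transformer additionally carries per-atom
  Cartesian vector features that rotate with the frame.

The tensor model represents each atom by channels of Cartesian 3x3 matrices
X = I + A + S (isotropic, antisymmetric, symmetric-traceless).  Under a
proper rotation R the features transform as X -> R X R^T and under an
improper operation as X -> R X^T R^T; every operation used (channel mixing,
symmetrized matrix products X M + M X and Y Y, Frobenius norms) commutes
with both, which is what makes the final scalar invariants exact under
reflections as well as rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .featurization import ExpNormalBasis, RadialConfig, cosine_cutoff
from .geometry import NeighborList
from .nn import MLP, Embedding, LayerNorm, Linear, Module

__all__ = [
    "RepresentationConfig",
    "EdgeData",
    "prepare_edges",
    "decompose_tensor",
    "TensorNetRepresentation",
    "EquivariantTransformer",
    "GraphNetwork",
    "build_representation",
    "AtomFeatures",
]

MODEL_NAMES = ("tensornet", "equivariant_transformer", "graph_network")


@dataclass(frozen=True)
class RepresentationConfig:
    model: str = "tensornet"
    embedding_dimension: int = 128
    num_layers: int = 2
    radial: RadialConfig = field(default_factory=RadialConfig)
    max_z: int = 100
    vector_cutoff: bool = True

    def __post_init__(self):
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")
        if self.embedding_dimension < 1:
            raise ValueError("embedding_dimension must be >= 1")
        if self.num_layers < 0:
            raise ValueError("num_layers must be >= 0")


@dataclass
class AtomFeatures:
    """Per-atom invariant features; vector features for the ET only."""

    scalar: Tensor  # (N, C)
    vector: Tensor | None = None  # (N, 3, C)


@dataclass
class EdgeData:
    """Differentiable edge geometry with ghost-atom index remapping."""

    src: np.ndarray  # (M,) padded slots point at the ghost index n_atoms
    tgt: np.ndarray
    dist: Tensor  # (M,)
    vec: Tensor  # (M, 3), exact zeros on padded slots
    unit: Tensor  # (M, 3), defined-zero at zero distance
    pad_mask: np.ndarray  # (M,) True on real slots
    n_atoms: int

    @property
    def n_nodes(self) -> int:
        """Real atoms plus the ghost."""
        return self.n_atoms + 1


def prepare_edges(positions: Tensor, neighbors: NeighborList) -> EdgeData:
    """Rebuild edge vectors/distances differentiably from positions.

    Uses the stored minimum-image shifts, which are locally constant, so
    gradients of anything built on the edges flow back to the positions
    (including through a second differentiation for force training).
    """
    n = positions.shape[0]
    mask = neighbors.real_mask
    src = np.where(mask, neighbors.pairs[0], n)
    tgt = np.where(mask, neighbors.pairs[1], n)
    pos_ext = ad.concatenate([positions, ad.constant(np.zeros((1, 3)))], axis=0)
    raw = ad.take(pos_ext, tgt) - ad.take(pos_ext, src)
    vec = ad.mul(
        ad.add(raw, ad.constant(neighbors.shifts)),
        ad.constant(mask.astype(positions.dtype)[:, None]),
    )
    dist = ad.tsqrt(ad.tsum(ad.mul(vec, vec), axis=1))
    unit = ad.safe_div(vec, dist.reshape((-1, 1)))
    return EdgeData(src, tgt, dist, vec, unit, mask, n)


def decompose_tensor(x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Split 3x3 matrices (stacked on trailing axes) into I, A, S parts.

    I is isotropic (trace part), A antisymmetric, S symmetric traceless;
    the decomposition is exact: x = I + A + S.
    """
    xt = x.swapaxes(-1, -2)
    eye = ad.constant(np.eye(3))
    trace = ad.tsum(ad.mul(x, eye), axis=(-2, -1), keepdims=True)
    i_part = ad.mul(eye, ad.mul(trace, 1.0 / 3.0))
    a_part = ad.mul(x - xt, 0.5)
    s_part = ad.mul(x + xt, 0.5) - i_part
    return i_part, a_part, s_part


def _frobenius_sq(x: Tensor) -> Tensor:
    return ad.tsum(ad.mul(x, x), axis=(-2, -1))


def _channel_mix(x: Tensor, weight) -> Tensor:
    """Linear mix over the channel axis of (N, C, 3, 3) tensor features."""
    moved = x.transpose((0, 2, 3, 1))  # (N, 3, 3, C)
    mixed = ad.matmul(moved, weight)
    return mixed.transpose((0, 3, 1, 2))


def _edge_basis_matrices(edges: EdgeData) -> tuple[Tensor, Tensor]:
    """Antisymmetric and symmetric-traceless 3x3 matrices of the unit vector."""
    u = edges.unit
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    zero = ad.constant(np.zeros(u.shape[0]))
    a_rows = ad.stack(
        [
            ad.stack([zero, -uz, uy], axis=1),
            ad.stack([uz, zero, -ux], axis=1),
            ad.stack([-uy, ux, zero], axis=1),
        ],
        axis=1,
    )  # (M, 3, 3)
    outer = ad.mul(u.reshape((-1, 3, 1)), u.reshape((-1, 1, 3)))
    norm_sq = ad.tsum(ad.mul(u, u), axis=1).reshape((-1, 1, 1))
    s_rows = outer - ad.mul(ad.constant(np.eye(3)), ad.mul(norm_sq, 1.0 / 3.0))
    return a_rows, s_rows


class TensorNetRepresentation(Module):
    """O(3)-invariant features from Cartesian rank-2 tensor channels.

    Clebsch-Gordan couplings are replaced by node-level 3x3 matrix products;
    the layer equations follow the Cartesian-tensor lineage with local
    choices of init and normalization.
    """

    def __init__(self, config: RepresentationConfig, rng: np.random.Generator):
        c = config.embedding_dimension
        self.config = config
        self.embedding = Embedding(config.max_z + 1, c, rng)
        self.basis = ExpNormalBasis(config.radial)
        k = config.radial.num_rbf
        self.edge_weight = Linear(k, 3 * c, rng)
        self.pair_gate = Linear(2 * c, 3 * c, rng)
        self.init_mix = [Linear(c, c, rng, bias=False) for _ in range(3)]
        self.layer_edge = [Linear(k, 3 * c, rng) for _ in range(config.num_layers)]
        self.layer_mix_in = [
            [Linear(c, c, rng, bias=False) for _ in range(3)]
            for _ in range(config.num_layers)
        ]
        self.layer_mix_out = [
            [Linear(c, c, rng, bias=False) for _ in range(3)]
            for _ in range(config.num_layers)
        ]
        self.readout = Linear(3 * c, c, rng)

    def _split3(self, w: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        c = self.config.embedding_dimension
        return w[:, :c], w[:, c : 2 * c], w[:, 2 * c :]

    def _mix_parts(self, x: Tensor, mixers) -> Tensor:
        i_p, a_p, s_p = decompose_tensor(x)
        return (
            _channel_mix(i_p, mixers[0].weight)
            + _channel_mix(a_p, mixers[1].weight)
            + _channel_mix(s_p, mixers[2].weight)
        )

    def __call__(self, z: np.ndarray, edges: EdgeData) -> AtomFeatures:
        c = self.config.embedding_dimension
        z_ext = np.concatenate([z, [0]])  # ghost atom embeds via index 0
        emb = self.embedding(z_ext)
        rbf = self.basis(edges.dist, edges.pad_mask)
        a_mat, s_mat = _edge_basis_matrices(edges)
        eye = ad.constant(np.broadcast_to(np.eye(3), (len(edges.src), 3, 3)).copy())
        mask = ad.constant(edges.pad_mask.astype(np.float64)[:, None])

        w = ad.mul(ad.silu(self.edge_weight(rbf)), mask)
        pair = ad.concatenate([ad.take(emb, edges.src), ad.take(emb, edges.tgt)], axis=1)
        w = ad.mul(w, ad.silu(self.pair_gate(pair)))
        w_i, w_a, w_s = self._split3(w)

        def edge_tensor(w_i, w_a, w_s):
            return (
                ad.mul(w_i.reshape((-1, c, 1, 1)), eye.reshape((-1, 1, 3, 3)))
                + ad.mul(w_a.reshape((-1, c, 1, 1)), a_mat.reshape((-1, 1, 3, 3)))
                + ad.mul(w_s.reshape((-1, c, 1, 1)), s_mat.reshape((-1, 1, 3, 3)))
            )

        x = ad.index_add(edge_tensor(w_i, w_a, w_s), edges.src, edges.n_nodes)
        x = self._normalize(x)
        x = self._mix_parts(x, self.init_mix)

        for layer in range(self.config.num_layers):
            y = self._mix_parts(x, self.layer_mix_in[layer])
            wl = ad.mul(ad.silu(self.layer_edge[layer](rbf)), mask)
            l_i, l_a, l_s = self._split3(wl)
            i_p, a_p, s_p = decompose_tensor(ad.take(y, edges.tgt))
            msg = (
                ad.mul(l_i.reshape((-1, c, 1, 1)), i_p)
                + ad.mul(l_a.reshape((-1, c, 1, 1)), a_p)
                + ad.mul(l_s.reshape((-1, c, 1, 1)), s_p)
            )
            m = ad.index_add(msg, edges.src, edges.n_nodes)
            prod = ad.matmul(x, m) + ad.matmul(m, x)
            prod = self._normalize(prod)
            prod = self._mix_parts(prod, self.layer_mix_out[layer])
            x = x + prod + ad.matmul(prod, prod)

        i_p, a_p, s_p = decompose_tensor(x)
        scalars = ad.concatenate(
            [_frobenius_sq(i_p), _frobenius_sq(a_p), _frobenius_sq(s_p)], axis=1
        )
        feats = ad.silu(self.readout(scalars))
        return AtomFeatures(scalar=feats[: edges.n_atoms])

    @staticmethod
    def _normalize(x: Tensor) -> Tensor:
        fro = ad.tsqrt(_frobenius_sq(x))
        return ad.mul(x, ad.power(ad.add(fro, 1.0), -1.0).reshape(fro.shape + (1, 1)))


class EquivariantTransformer(Module):
    """Scalar + Cartesian-vector features with distance-gated attention.

    The value pathway of the attention mechanism feeds the vector-feature
    residual updates.  Historically those contributions were not weighted by
    the cosine cutoff envelope, leaving a discontinuity in the potential at
    r_c; with ``vector_cutoff`` on, the value-pathway vector contribution is
    multiplied by phi(d_ij) so every edge term vanishes continuously at the
    cutoff.  With it off the legacy discontinuous behaviour is reproduced.
    """

    def __init__(self, config: RepresentationConfig, rng: np.random.Generator):
        c = config.embedding_dimension
        k = config.radial.num_rbf
        self.config = config
        self.embedding = Embedding(config.max_z + 1, c, rng)
        self.basis = ExpNormalBasis(config.radial)
        self.norms = [LayerNorm(c) for _ in range(config.num_layers)]
        self.q_proj = [Linear(c, c, rng) for _ in range(config.num_layers)]
        self.k_proj = [Linear(c, c, rng) for _ in range(config.num_layers)]
        self.v_proj = [Linear(c, 3 * c, rng) for _ in range(config.num_layers)]
        self.dk_proj = [Linear(k, c, rng) for _ in range(config.num_layers)]
        self.dv_proj = [Linear(k, 3 * c, rng) for _ in range(config.num_layers)]
        self.u_proj = [Linear(c, c, rng, bias=False) for _ in range(config.num_layers)]
        self.w_proj = [Linear(c, c, rng, bias=False) for _ in range(config.num_layers)]
        self.update = [MLP([2 * c, c, 3 * c], rng) for _ in range(config.num_layers)]

    def __call__(self, z: np.ndarray, edges: EdgeData) -> AtomFeatures:
        c = self.config.embedding_dimension
        cutoff = self.config.radial.cutoff
        z_ext = np.concatenate([z, [0]])
        x = self.embedding(z_ext)
        v = ad.constant(np.zeros((edges.n_nodes, 3, c)))
        # value-pathway filters use the raw (non-enveloped) basis: the
        # legacy/fixed distinction at the cutoff lives exactly here
        rbf_raw = self._raw_basis(edges)
        mask = edges.pad_mask.astype(np.float64)
        phi = ad.mul(cosine_cutoff(edges.dist, cutoff), ad.constant(mask))

        for layer in range(self.config.num_layers):
            xn = self.norms[layer](x)
            q = self.q_proj[layer](xn)
            kk = self.k_proj[layer](xn)
            val = self.v_proj[layer](xn)
            dk = ad.silu(self.dk_proj[layer](rbf_raw))
            dv = ad.silu(self.dv_proj[layer](rbf_raw))
            attn = ad.tsum(
                ad.mul(ad.mul(ad.take(q, edges.src), ad.take(kk, edges.tgt)), dk),
                axis=1,
            )
            attn = ad.mul(ad.silu(attn), phi)
            vj = ad.mul(ad.take(val, edges.tgt), dv)
            x_h, s1, s2 = vj[:, :c], vj[:, c : 2 * c], vj[:, 2 * c :]
            dx = ad.index_add(
                ad.mul(x_h, attn.reshape((-1, 1))), edges.src, edges.n_nodes
            )
            vec_term = ad.mul(
                s1.reshape((-1, 1, c)), ad.take(v, edges.tgt)
            ) + ad.mul(s2.reshape((-1, 1, c)), edges.unit.reshape((-1, 3, 1)))
            if self.config.vector_cutoff:
                vec_term = ad.mul(vec_term, phi.reshape((-1, 1, 1)))
            else:
                vec_term = ad.mul(vec_term, ad.constant(mask[:, None, None]))
            dvec = ad.index_add(vec_term, edges.src, edges.n_nodes)
            x = x + dx
            v = v + dvec

            uv = ad.matmul(v, self.u_proj[layer].weight)
            wv = ad.matmul(v, self.w_proj[layer].weight)
            inner = ad.tsum(ad.mul(uv, wv), axis=1)  # (N, C), O(3)-invariant
            o = self.update[layer](ad.concatenate([x, inner], axis=1))
            o1, o2, o3 = o[:, :c], o[:, c : 2 * c], o[:, 2 * c :]
            x = x + o1 + ad.mul(o2, inner)
            v = v + ad.mul(o3.reshape((-1, 1, c)), uv)

        n = edges.n_atoms
        return AtomFeatures(scalar=x[:n], vector=v[:n])

    def _raw_basis(self, edges: EdgeData) -> Tensor:
        d = edges.dist.reshape((-1, 1))
        diff = ad.texp(ad.mul(d, -1.0)) - self.basis.means
        feats = ad.texp(ad.mul(ad.mul(self.basis.betas, ad.mul(diff, diff)), -1.0))
        return ad.mul(feats, ad.constant(edges.pad_mask.astype(np.float64)[:, None]))


class GraphNetwork(Module):
    """Invariant continuous-filter convolutions over radial features.

    Uses only interatomic distances, so invariance to translations,
    rotations and reflections holds by construction.
    """

    def __init__(self, config: RepresentationConfig, rng: np.random.Generator):
        c = config.embedding_dimension
        k = config.radial.num_rbf
        self.config = config
        self.embedding = Embedding(config.max_z + 1, c, rng)
        self.basis = ExpNormalBasis(config.radial)
        self.filters = [MLP([k, c, c], rng) for _ in range(config.num_layers)]
        self.pre = [Linear(c, c, rng) for _ in range(config.num_layers)]
        self.post = [Linear(c, c, rng) for _ in range(config.num_layers)]

    def __call__(self, z: np.ndarray, edges: EdgeData) -> AtomFeatures:
        z_ext = np.concatenate([z, [0]])
        x = self.embedding(z_ext)
        rbf = self.basis(edges.dist, edges.pad_mask)
        mask = ad.constant(edges.pad_mask.astype(np.float64)[:, None])
        for layer in range(self.config.num_layers):
            w = ad.mul(self.filters[layer](rbf), mask)
            msg = ad.mul(w, ad.take(self.pre[layer](x), edges.tgt))
            agg = ad.index_add(msg, edges.src, edges.n_nodes)
            x = x + self.post[layer](ad.silu(agg))
        return AtomFeatures(scalar=x[: edges.n_atoms])


def build_representation(
    config: RepresentationConfig, rng: np.random.Generator
) -> Module:
    cls = {
        "tensornet": TensorNetRepresentation,
        "equivariant_transformer": EquivariantTransformer,
        "graph_network": GraphNetwork,
    }[config.model]
    return cls(config, rng)
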