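"""Physical prior energies added to the learned potential.

Priors act at one of two levels: atom-level terms modify per-atom energies
before the per-sample reduction (reference energies), and sample-level terms
add pairwise analytic energies after it (electrostatics, dispersion, nuclear
repulsion).  All prior contributions are added *before* any gradient is
taken, so forces automatically include them.

Pairwise sums run over the half list (each unordered pair once).  The ZBL
term carries the cosine cutoff envelope and vanishes continuously at the
neighbor cutoff; Coulomb and D2 are plainly truncated there, which leaves a
small, documented discontinuity (no long-range corrections are applied).

Numeric tables (ZBL screening constants, per-element D2 C6 coefficients and
van der Waals radii) ship as data files under ``mlpot/tables`` and are
treated as data, not code.
"""

from __future__ import annotations

import csv
from importlib import resources

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor
from .featurization import cosine_cutoff
from .geometry import ParticleSystem
from .nn import Module, Parameter
from .representations import EdgeData
from .units import COULOMB_CONSTANT_EV, D2_C6_JNM6_TO_EV

__all__ = [
    "BasePrior",
    "AtomrefPrior",
    "CoulombPrior",
    "ZBLPrior",
    "D2Prior",
    "apply_priors",
    "build_prior",
    "load_d2_table",
    "load_zbl_constants",
]


class PriorConfigurationError(ValueError):
    pass


def load_d2_table() -> dict[int, tuple[float, float]]:
    """Bundled per-element (C6 [J nm^6/mol], vdW radius [Å]) table."""
    text = resources.files("mlpot").joinpath("tables/d2_params.csv").read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    table = {}
    for rec in csv.DictReader(rows):
        table[int(rec["z"])] = (float(rec["c6"]), float(rec["r_vdw"]))
    return table


def load_zbl_constants() -> dict:
    text = resources.files("mlpot").joinpath("tables/zbl_params.yaml").read_text()
    return yaml.safe_load(text)


class BasePrior(Module):
    """Extension point: override either hook; both default to identity.

    ``atom_level`` receives and returns per-atom energies (N,);
    ``sample_level`` receives and returns per-sample energies (B,).
    Any object with these two hooks composes identically to the built-ins.
    """

    def atom_level(
        self, per_atom: Tensor, system: ParticleSystem, edges: EdgeData
    ) -> Tensor:
        return per_atom

    def sample_level(
        self,
        per_sample: Tensor,
        system: ParticleSystem,
        edges: EdgeData,
        n_batches: int,
    ) -> Tensor:
        return per_sample

    def to_spec(self) -> dict:
        raise NotImplementedError


def _half_mask(edges: EdgeData) -> np.ndarray:
    """Each unordered real pair once: real slots with source < target."""
    return edges.pad_mask & (edges.src < edges.tgt)


def _edge_batch(edges: EdgeData, system: ParticleSystem) -> np.ndarray:
    """Sample index per edge; padded slots (ghost source) map to 0, masked."""
    batch_ext = np.concatenate([system.batch, [0]])
    return batch_ext[edges.src]


def _scatter_pair_energy(
    e_edge: Tensor, edges: EdgeData, system: ParticleSystem, n_batches: int
) -> Tensor:
    mask = _half_mask(edges)
    e_edge = ad.mul(e_edge, ad.constant(mask.astype(np.float64)))
    return ad.index_add(
        e_edge.reshape((-1, 1)), _edge_batch(edges, system), n_batches
    ).reshape((-1,))


class AtomrefPrior(BasePrior):
    """Per-element reference energies, optionally learnable.

    Subtracting (or learning) these offsets leaves the network to fit the
    much smaller formation-energy-like residual.
    """

    def __init__(self, table: np.ndarray, trainable: bool = False):
        table = np.asarray(table, dtype=np.float64).ravel()
        self.table = Parameter(table, requires_grad=trainable)
        self.trainable = trainable

    def atom_level(self, per_atom, system, edges):
        z = system.atomic_numbers
        if z.size and z.max() >= self.table.shape[0]:
            missing = sorted(set(z[z >= self.table.shape[0]].tolist()))
            raise PriorConfigurationError(
                f"atomref table (size {self.table.shape[0]}) does not cover "
                f"elements {missing}"
            )
        return per_atom + ad.take(self.table, z)

    def to_spec(self) -> dict:
        return {
            "kind": "atomref",
            "table": self.table.data.tolist(),
            "trainable": self.trainable,
        }


class CoulombPrior(BasePrior):
    """Pairwise electrostatics with a short-range cosine switching function.

    E = sum_pairs sw(r) * k q_i q_j / r with sw(r) = (1 - cos(pi r / r_sw))/2
    below the switching distance and 1 beyond it: the switch removes the
    r -> 0 singularity and leaves full Coulomb at r >= r_sw.  Requires
    per-atom partial charges on the system.
    """

    def __init__(self, switching_distance: float, k: float = COULOMB_CONSTANT_EV):
        if switching_distance <= 0:
            raise ValueError("switching_distance must be positive")
        self.switching_distance = switching_distance
        self.k = k

    def sample_level(self, per_sample, system, edges, n_batches):
        if system.charges is None:
            raise PriorConfigurationError(
                "coulomb prior requires per-atom partial charges on the system"
            )
        q_ext = ad.constant(np.concatenate([system.charges, [0.0]]))
        qq = ad.mul(ad.take(q_ext, edges.src), ad.take(q_ext, edges.tgt))
        r = edges.dist
        r_sw = self.switching_distance
        inside = r.data < r_sw
        sw_in = ad.mul(1.0 - ad.tcos(ad.mul(r, np.pi / r_sw)), 0.5)
        sw = ad.where_mask(inside, sw_in, ad.constant(np.ones_like(r.data)))
        e = ad.mul(ad.mul(sw, qq), ad.safe_div(ad.constant(self.k), r))
        return per_sample + _scatter_pair_energy(e, edges, system, n_batches)

    def to_spec(self) -> dict:
        return {
            "kind": "coulomb",
            "switching_distance": self.switching_distance,
            "k": self.k,
        }


class ZBLPrior(BasePrior):
    """Ziegler-Biersack-Littmark screened nuclear repulsion.

    E = sum_pairs phi_cut(r) * (k Z_i Z_j / r) * f(r / a_ij) with the
    four-exponential universal screening function f and screening length
    a_ij = a0 / (Z_i^p + Z_j^p).  The cosine cutoff envelope phi_cut takes
    every contribution continuously to zero at the neighbor cutoff.  Only
    atomic numbers are needed.
    """

    def __init__(self, cutoff: float, k: float = COULOMB_CONSTANT_EV, constants: dict | None = None):
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        c = constants or load_zbl_constants()
        self.coefficients = np.asarray(c["coefficients"], dtype=np.float64)
        self.exponents = np.asarray(c["exponents"], dtype=np.float64)
        self.length_prefactor = float(c["length_prefactor"])
        self.length_exponent = float(c["length_exponent"])
        self.cutoff = cutoff
        self.k = k

    def screening_function(self, x: Tensor | np.ndarray) -> Tensor:
        """f(x) = sum_i c_i exp(-e_i x); f(0) equals the coefficient sum."""
        x = ad.as_tensor(x)
        xcol = x.reshape(x.shape + (1,))
        terms = ad.texp(ad.mul(xcol, ad.constant(-self.exponents)))
        return ad.tsum(ad.mul(terms, ad.constant(self.coefficients)), axis=-1)

    def sample_level(self, per_sample, system, edges, n_batches):
        z_ext = np.concatenate([system.atomic_numbers, [1]]).astype(np.float64)
        zi, zj = z_ext[edges.src], z_ext[edges.tgt]
        a = self.length_prefactor / (
            zi**self.length_exponent + zj**self.length_exponent
        )
        r = edges.dist
        x = ad.mul(r, ad.constant(1.0 / a))
        f = self.screening_function(x)
        bare = ad.mul(
            ad.safe_div(ad.constant(self.k * zi * zj), r), f
        )
        e = ad.mul(bare, cosine_cutoff(r, self.cutoff))
        return per_sample + _scatter_pair_energy(e, edges, system, n_batches)

    def to_spec(self) -> dict:
        return {"kind": "zbl", "cutoff": self.cutoff, "k": self.k}


class D2Prior(BasePrior):
    """DFT-D2 dispersion: E = -s6 sum_pairs f_dmp(r) C6_ij / r^6.

    C6_ij is the geometric mean of per-element coefficients and
    f_dmp(r) = 1 / (1 + exp(-d (r / R_ij - 1))) with R_ij the summed van der
    Waals radii; element tables ship with the package.  ``c6_conversion``
    scales the tabulated C6 (J nm^6/mol) into the working energy unit;
    the default targets eV with distances in Å.
    """

    def __init__(
        self,
        s6: float = 1.0,
        d: float = 20.0,
        c6_conversion: float = D2_C6_JNM6_TO_EV,
        table: dict[int, tuple[float, float]] | None = None,
    ):
        self.s6 = s6
        self.d = d
        self.c6_conversion = c6_conversion
        self.table = table or load_d2_table()

    def _element_arrays(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        missing = sorted(set(z.tolist()) - set(self.table))
        if missing:
            raise PriorConfigurationError(
                f"D2 parameters missing for elements {missing}"
            )
        c6 = np.array([self.table[int(s)][0] for s in z]) * self.c6_conversion
        rv = np.array([self.table[int(s)][1] for s in z])
        return c6, rv

    def sample_level(self, per_sample, system, edges, n_batches):
        c6_el, rv_el = self._element_arrays(system.atomic_numbers)
        c6_ext = np.concatenate([c6_el, [0.0]])
        rv_ext = np.concatenate([rv_el, [1.0]])
        c6 = np.sqrt(c6_ext[edges.src] * c6_ext[edges.tgt])
        r_ij = rv_ext[edges.src] + rv_ext[edges.tgt]
        r = edges.dist
        fdmp = ad.sigmoid(
            ad.mul(ad.mul(r, ad.constant(1.0 / r_ij)) - 1.0, self.d)
        )
        r6 = ad.mul(ad.mul(ad.mul(r, r), ad.mul(r, r)), ad.mul(r, r))
        e = ad.mul(ad.mul(fdmp, ad.safe_div(ad.constant(c6), r6)), -self.s6)
        return per_sample + _scatter_pair_energy(e, edges, system, n_batches)

    def to_spec(self) -> dict:
        return {
            "kind": "d2",
            "s6": self.s6,
            "d": self.d,
            "c6_conversion": self.c6_conversion,
        }


def build_prior(spec: dict, cutoff: float | None = None) -> BasePrior:
    """Construct a prior from its configuration dictionary."""
    spec = dict(spec)
    kind = spec.pop("kind")
    if kind == "atomref":
        return AtomrefPrior(np.asarray(spec["table"]), spec.get("trainable", False))
    if kind == "coulomb":
        return CoulombPrior(spec["switching_distance"], spec.get("k", COULOMB_CONSTANT_EV))
    if kind == "zbl":
        return ZBLPrior(spec.get("cutoff", cutoff), k=spec.get("k", COULOMB_CONSTANT_EV))
    if kind == "d2":
        return D2Prior(
            s6=spec.get("s6", 1.0),
            d=spec.get("d", 20.0),
            c6_conversion=spec.get("c6_conversion", D2_C6_JNM6_TO_EV),
        )
    raise PriorConfigurationError(f"unknown prior kind {kind!r}")


def apply_priors(
    per_atom: Tensor,
    system: ParticleSystem,
    edges: EdgeData,
    n_batches: int,
    priors: list[BasePrior],
    reduce_op: str = "sum",
) -> tuple[Tensor, Tensor]:
    """Compose atom-level priors, the reduction, and sample-level priors.

    Atom-level hooks run before the per-sample reduction; sample-level hooks
    after it.  Returns the modified per-atom energies and the final
    per-sample energies.  An empty prior list is the identity composition.
    """
    from .outputs import reduce_per_sample

    for prior in priors:
        per_atom = prior.atom_level(per_atom, system, edges)
    per_sample = reduce_per_sample(per_atom, system.batch, n_batches, reduce_op)
    for prior in priors:
        per_sample = prior.sample_level(per_sample, system, edges, n_batches)
    return per_atom, per_sample
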