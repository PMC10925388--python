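"""Seeded generators for every test input: particle clouds and toy datasets.

Nothing here is downloaded or read from disk; all inputs used by the test
suite and the validation scripts are generated from (spec, seed) pairs and
are bit-reproducible.  Writers emit the generated datasets in both on-disk
layouts so loader tests are pure round-trips.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import ConformerDataset, ConformerRecord, write_hdf5
from .geometry import ParticleSystem, SimulationBox, brute_force_neighbors

__all__ = [
    "CloudSpec",
    "make_cloud",
    "make_dimer_dataset",
    "make_atomref_dataset",
    "morse_potential",
    "write_custom_numpy",
]

#: small organic-chemistry element set; keeps prior tables compact
CLOUD_ELEMENTS = (1, 6, 7, 8, 16)


@dataclass(frozen=True)
class CloudSpec:
    """Random particle cloud with a target mean neighbor count.

    The box edge is sized from the ideal-gas relation
    density = target_neighbors / ((4/3) pi r_c^3); the realized mean
    neighbor count is checked to be within 20% of the target.
    """

    n_atoms: int
    target_neighbors: float
    cutoff: float
    box_kind: str = "rectangular"  # open | rectangular | triclinic
    n_batches: int = 1
    seed: int = 0
    check_density: bool = True

    def __post_init__(self):
        if self.box_kind not in ("open", "rectangular", "triclinic"):
            raise ValueError(f"unknown box kind {self.box_kind!r}")
        if self.n_atoms < self.n_batches:
            raise ValueError("need at least one atom per batch")


def make_cloud(spec: CloudSpec) -> ParticleSystem:
    """Uniform random cloud; deterministic under (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    density = spec.target_neighbors / (4.0 / 3.0 * np.pi * spec.cutoff**3)
    per_batch = spec.n_atoms // spec.n_batches
    volume = per_batch / density
    edge = volume ** (1.0 / 3.0)
    if edge < 2.0 * spec.cutoff and spec.box_kind != "open":
        if spec.n_batches == 1:
            raise ValueError(
                f"infeasible density: box edge {edge:.2f} Å < 2 r_c "
                f"= {2 * spec.cutoff:.2f} Å; lower target_neighbors or raise n_atoms"
            )
        # batched clouds share one box; grow it to the smallest valid size
        edge = 2.0 * spec.cutoff
    if spec.box_kind == "open":
        box = None
    elif spec.box_kind == "rectangular":
        box = SimulationBox(np.diag([edge, edge, edge]))
    else:
        skew = 0.2 * edge  # stays inside the reduced-form constraints
        lat = np.array(
            [[edge, 0, 0], [skew, edge, 0], [skew, -skew, edge]]
        )
        box = SimulationBox(lat)
    counts = np.full(spec.n_batches, per_batch)
    counts[: spec.n_atoms - per_batch * spec.n_batches] += 1
    positions = rng.uniform(0.0, edge, size=(spec.n_atoms, 3))
    batch = np.repeat(np.arange(spec.n_batches), counts)
    z = rng.choice(CLOUD_ELEMENTS, size=spec.n_atoms)
    system = ParticleSystem(positions, z, batch=batch, box=box)
    if spec.check_density and spec.n_atoms >= 100 and spec.n_batches == 1:
        nl = brute_force_neighbors(system, spec.cutoff, include_transpose=True)
        realized = nl.n_found / spec.n_atoms
        if not 0.8 * spec.target_neighbors <= realized <= 1.2 * spec.target_neighbors:
            raise ValueError(
                f"realized mean neighbor count {realized:.1f} outside 20% of "
                f"target {spec.target_neighbors}"
            )
    return system


def morse_potential(
    depth: float = 1.0, a: float = 1.5, r0: float = 1.5
) -> tuple[Callable, Callable]:
    """Smooth analytic pair potential V(r) and its derivative dV/dr."""

    def v(r):
        e = np.exp(-a * (r - r0))
        return depth * (1.0 - e) ** 2 - depth

    def dv(r):
        e = np.exp(-a * (r - r0))
        return 2.0 * depth * a * e * (1.0 - e)

    return v, dv


def make_dimer_dataset(
    n_samples: int = 200,
    r_range: tuple[float, float] = (1.0, 4.0),
    pair_potential: tuple[Callable, Callable] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    elements: tuple[int, int] = (6, 8),
) -> ConformerDataset:
    """Two-atom conformers on a smooth pair potential, with exact forces.

    Energies are V(r) (+ optional Gaussian noise); stored forces are the
    exact analytic ones, -dV/dr along the bond, so force-matching tests have
    a known ground truth.
    """
    v, dv = pair_potential or morse_potential()
    rng = np.random.default_rng(seed)
    ds = ConformerDataset()
    z = np.array(elements)
    for _ in range(n_samples):
        r = rng.uniform(*r_range)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = np.vstack([np.zeros(3), r * direction])
        y = v(r) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        grad = dv(r) * direction  # dV/dr_1
        neg_dy = np.vstack([grad, -grad])
        ds.append(ConformerRecord(z, pos, y, neg_dy=neg_dy))
    return ds


def make_atomref_dataset(
    n_samples: int = 500,
    element_set: tuple[int, ...] = CLOUD_ELEMENTS,
    mu_table: dict[int, float] | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    atoms_per_sample: tuple[int, int] = (2, 8),
) -> tuple[ConformerDataset, dict[int, float]]:
    """Random compositions with y = sum_i mu(z_i) + noise and zero forces.

    Used to check that a learnable per-element reference table recovers the
    generating offsets.  Returns the dataset and the mu table it used.
    """
    rng = np.random.default_rng(seed)
    if mu_table is None:
        mu_table = {
            int(z): float(mu)
            for z, mu in zip(element_set, rng.uniform(-5.0, 5.0, len(element_set)))
        }
    ds = ConformerDataset()
    for _ in range(n_samples):
        n = int(rng.integers(*atoms_per_sample))
        z = rng.choice(list(element_set), size=n)
        # positions spread out so geometry carries no signal
        pos = rng.uniform(0.0, 20.0, size=(n, 3))
        y = sum(mu_table[int(s)] for s in z)
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd)
        ds.append(ConformerRecord(z, pos, y, neg_dy=np.zeros((n, 3))))
    return ds, mu_table


def write_custom_numpy(dataset: ConformerDataset, directory: str) -> dict[str, str]:
    """Write the custom NPY layout, grouping records by atom-type vector.

    Returns the glob patterns that :func:`mlpot.data.load_custom_numpy`
    accepts.  One embedding file is shared by all conformers of a molecule.
    """
    os.makedirs(directory, exist_ok=True)
    groups: dict[bytes, list[ConformerRecord]] = {}
    for rec in dataset.records:
        groups.setdefault(rec.z.tobytes(), []).append(rec)
    have_forces = dataset.has_forces
    for gi, recs in enumerate(groups.values()):
        tag = f"mol_{gi:05d}"
        np.save(os.path.join(directory, f"{tag}.coord.npy"),
                np.stack([r.pos for r in recs]))
        np.save(os.path.join(directory, f"{tag}.embed.npy"), recs[0].z)
        np.save(os.path.join(directory, f"{tag}.energy.npy"),
                np.array([[r.y] for r in recs]))
        if have_forces:
            np.save(os.path.join(directory, f"{tag}.forces.npy"),
                    np.stack([r.neg_dy for r in recs]))
    globs = {
        "coordglob": os.path.join(directory, "*.coord.npy"),
        "embedglob": os.path.join(directory, "*.embed.npy"),
        "energyglob": os.path.join(directory, "*.energy.npy"),
    }
    if have_forces:
        globs["forceglob"] = os.path.join(directory, "*.forces.npy")
    return globs


def write_fixture_hdf5(dataset: ConformerDataset, path: str) -> str:
    write_hdf5(dataset, path)
    return path
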