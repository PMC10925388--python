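"""Conformer datasets: in-memory container, array/HDF5 loaders, splits, XYZ.

Two on-disk layouts are supported:

* the "custom" numpy layout — per molecule, aligned files holding
  ``coords (n_conf, n_atoms, 3)``, ``embeddings (n_atoms,)`` (atomic
  numbers, shared by all conformers of the molecule), ``energies
  (n_conf, 1)`` and optionally ``forces (n_conf, n_atoms, 3)``, matched up
  by sorted glob patterns;
* an HDF5 layout — one group per molecule with datasets ``types``, ``pos``,
  ``energy`` and optionally ``forces`` / ``charges``.

Records are (z, pos, y, optional neg_dy, optional q); atom counts may differ
between molecules.
"""

from __future__ import annotations

import glob as globmod
from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "ConformerRecord",
    "ConformerDataset",
    "load_custom_numpy",
    "load_hdf5",
    "write_hdf5",
    "SplitSpec",
    "make_splits",
    "save_splits",
    "load_splits",
    "read_xyz",
    "write_xyz",
    "SYMBOL_TO_Z",
    "Z_TO_SYMBOL",
]

_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe"
).split()
SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
Z_TO_SYMBOL = {i + 1: s for i, s in enumerate(_SYMBOLS)}


@dataclass
class ConformerRecord:
    z: np.ndarray  # (n,)
    pos: np.ndarray  # (n, 3)
    y: float
    neg_dy: np.ndarray | None = None  # (n, 3)
    q: np.ndarray | None = None  # (n,)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.int64).ravel()
        self.pos = np.asarray(self.pos, dtype=np.float64).reshape(-1, 3)
        n = len(self.z)
        if self.pos.shape[0] != n:
            raise ValueError("record z/pos shape mismatch")
        self.y = float(self.y)
        if not np.isfinite(self.y):
            raise ValueError("record energy is not finite")
        if self.neg_dy is not None:
            self.neg_dy = np.asarray(self.neg_dy, dtype=np.float64).reshape(-1, 3)
            if self.neg_dy.shape[0] != n:
                raise ValueError("record force shape mismatch")
        if self.q is not None:
            self.q = np.asarray(self.q, dtype=np.float64).ravel()
            if self.q.shape[0] != n:
                raise ValueError("record charge shape mismatch")


class ConformerDataset:
    """Indexed collection of conformer records."""

    def __init__(self, records: list[ConformerRecord] | None = None):
        self.records = list(records or [])

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> ConformerRecord:
        return self.records[i]

    def append(self, record: ConformerRecord) -> None:
        self.records.append(record)

    @property
    def has_forces(self) -> bool:
        return len(self) > 0 and all(r.neg_dy is not None for r in self.records)

    @property
    def has_charges(self) -> bool:
        return len(self) > 0 and all(r.q is not None for r in self.records)


def _resolve_globs(*patterns: str | None) -> list[tuple[str | None, ...]]:
    groups = [sorted(globmod.glob(p)) if p else None for p in patterns]
    sizes = {len(g) for g in groups if g is not None}
    if len(sizes) > 1:
        raise ValueError(
            f"glob patterns resolve to differing file counts: "
            f"{[(p, len(g)) for p, g in zip(patterns, groups) if g is not None]}"
        )
    n = sizes.pop() if sizes else 0
    return [
        tuple(g[i] if g is not None else None for g in groups) for i in range(n)
    ]


def _load_array(path: str) -> np.ndarray:
    arr = np.load(path)
    if isinstance(arr, np.lib.npyio.NpzFile):
        keys = list(arr.keys())
        if len(keys) != 1:
            raise ValueError(f"{path}: expected a single array, found {keys}")
        arr = arr[keys[0]]
    return np.asarray(arr)


def load_custom_numpy(
    coordglob: str,
    embedglob: str,
    energyglob: str,
    forceglob: str | None = None,
) -> ConformerDataset:
    """Load the custom NPY/NPZ layout (one file group per molecule)."""
    ds = ConformerDataset()
    for cf, ef, yf, ff in _resolve_globs(coordglob, embedglob, energyglob, forceglob):
        coords = _load_array(cf)
        z = _load_array(ef).astype(np.int64).ravel()
        energies = _load_array(yf).reshape(-1)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"{cf}: coords must have shape (n_conf, n_atoms, 3)")
        if coords.shape[1] != len(z):
            raise ValueError(
                f"atom count mismatch between {cf} ({coords.shape[1]}) and "
                f"{ef} ({len(z)})"
            )
        if coords.shape[0] != len(energies):
            raise ValueError(
                f"conformer count mismatch between {cf} ({coords.shape[0]}) "
                f"and {yf} ({len(energies)})"
            )
        forces = None
        if ff is not None:
            forces = _load_array(ff)
            if forces.shape != coords.shape:
                raise ValueError(
                    f"force/coordinate shape mismatch between {ff} "
                    f"{forces.shape} and {cf} {coords.shape}"
                )
        for i in range(coords.shape[0]):
            ds.append(
                ConformerRecord(
                    z, coords[i], energies[i],
                    neg_dy=None if forces is None else forces[i],
                )
            )
    return ds


def load_hdf5(path: str, in_memory: bool = True) -> ConformerDataset:
    """Load the HDF5 group-per-molecule layout.

    With ``in_memory=False`` arrays stay backed by the (still open) file and
    are materialized per record on access, which is the memory-mapped mode
    for datasets larger than RAM.
    """
    f = h5py.File(path, "r")
    try:
        ds = _HDF5Dataset(f) if not in_memory else None
        if ds is not None:
            return ds
        out = ConformerDataset()
        for name in sorted(f.keys()):
            grp = f[name]
            _check_group(grp, name)
            z = grp["types"][...].astype(np.int64)
            pos = grp["pos"][...]
            energy = np.asarray(grp["energy"][...]).reshape(-1)
            forces = grp["forces"][...] if "forces" in grp else None
            charges = grp["charges"][...] if "charges" in grp else None
            for i in range(pos.shape[0]):
                out.append(
                    ConformerRecord(
                        z, pos[i], energy[i],
                        neg_dy=None if forces is None else forces[i],
                        q=charges,
                    )
                )
        return out
    finally:
        if in_memory:
            f.close()


def _check_group(grp, name: str) -> None:
    for key in ("types", "pos", "energy"):
        if key not in grp:
            raise ValueError(f"malformed HDF5 layout: group '{name}' lacks '{key}'")


class _HDF5Dataset(ConformerDataset):
    """Lazy view over an open HDF5 file; records built on access."""

    def __init__(self, handle: h5py.File):
        super().__init__()
        self._handle = handle
        self._index: list[tuple[str, int]] = []
        for name in sorted(handle.keys()):
            _check_group(handle[name], name)
            n_conf = handle[name]["pos"].shape[0]
            self._index.extend((name, i) for i in range(n_conf))

    def __len__(self) -> int:
        return len(self._index)

    def __getitem__(self, i: int) -> ConformerRecord:
        name, j = self._index[i]
        grp = self._handle[name]
        return ConformerRecord(
            grp["types"][...].astype(np.int64),
            grp["pos"][j],
            np.asarray(grp["energy"][...]).reshape(-1)[j],
            neg_dy=grp["forces"][j] if "forces" in grp else None,
            q=grp["charges"][...] if "charges" in grp else None,
        )

    @property
    def records(self):  # type: ignore[override]
        return [self[i] for i in range(len(self))]

    @records.setter
    def records(self, value):
        if value:
            raise TypeError("HDF5-backed datasets are read-only")


def write_hdf5(dataset: ConformerDataset, path: str) -> None:
    """Write records grouped by identical atom-type vectors."""
    groups: dict[bytes, list[ConformerRecord]] = {}
    for rec in dataset.records:
        groups.setdefault(rec.z.tobytes(), []).append(rec)
    with h5py.File(path, "w") as f:
        for gi, recs in enumerate(groups.values()):
            grp = f.create_group(f"mol_{gi:05d}")
            grp.create_dataset("types", data=recs[0].z)
            grp.create_dataset("pos", data=np.stack([r.pos for r in recs]))
            grp.create_dataset("energy", data=np.array([[r.y] for r in recs]))
            if all(r.neg_dy is not None for r in recs):
                grp.create_dataset(
                    "forces", data=np.stack([r.neg_dy for r in recs])
                )
            if all(r.q is not None for r in recs):
                grp.create_dataset("charges", data=recs[0].q)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test sizes as counts (int) or fractions (float), plus seed."""

    train: int | float
    val: int | float
    test: int | float
    seed: int = 0


def _resolve_size(x: int | float, n: int) -> int:
    if isinstance(x, float) and 0 <= x <= 1:
        return int(round(x * n))
    return int(x)


def make_splits(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, seed-deterministic shuffled train/val/test index arrays."""
    n_train = _resolve_size(spec.train, n)
    n_val = _resolve_size(spec.val, n)
    n_test = _resolve_size(spec.test, n)
    if n_train + n_val + n_test > n:
        raise ValueError(
            f"split sizes {n_train}/{n_val}/{n_test} oversubscribe {n} samples"
        )
    perm = np.random.default_rng(spec.seed).permutation(n)
    train = np.sort(perm[:n_train])
    val = np.sort(perm[n_train : n_train + n_val])
    test = np.sort(perm[n_train + n_val : n_train + n_val + n_test])
    return train, val, test


def save_splits(path: str, train, val, test) -> None:
    np.savez(path, idx_train=train, idx_val=val, idx_test=test)


def load_splits(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with np.load(path) as f:
        return f["idx_train"], f["idx_val"], f["idx_test"]


# ---------------------------------------------------------------------------
# XYZ structures for inference
# ---------------------------------------------------------------------------


def read_xyz(path: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read concatenated XYZ blocks; returns [(z, pos), ...].

    Atom counts may differ between blocks.  Element symbols are mapped to
    atomic numbers; bare numbers are accepted as atomic numbers directly.
    """
    structures = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise ValueError(f"{path}:{i + 1}: expected an atom count") from err
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError(f"{path}: truncated XYZ block at line {i + 1}")
        z = np.empty(n, dtype=np.int64)
        pos = np.empty((n, 3))
        for j, ln in enumerate(body):
            parts = ln.split()
            sym = parts[0]
            if sym in SYMBOL_TO_Z:
                z[j] = SYMBOL_TO_Z[sym]
            else:
                try:
                    z[j] = int(sym)
                except ValueError as err:
                    raise ValueError(
                        f"{path}: unknown element symbol {sym!r}"
                    ) from err
            pos[j] = [float(p) for p in parts[1:4]]
        structures.append((z, pos))
        i += 2 + n
    return structures


def write_xyz(path: str, structures, comments=None) -> None:
    with open(path, "w") as fh:
        for idx, (z, pos) in enumerate(structures):
            comment = comments[idx] if comments else ""
            fh.write(f"{len(z)}\n{comment}\n")
            for zi, p in zip(z, np.asarray(pos)):
                sym = Z_TO_SYMBOL.get(int(zi), str(int(zi)))
                fh.write(f"{sym} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")
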