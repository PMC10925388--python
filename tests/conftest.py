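import numpy as np
import pytest

from mlpot.featurization import RadialConfig
from mlpot.geometry import ParticleSystem, SimulationBox
from mlpot.representations import RepresentationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_system(rng):
    """10 atoms, one batch, open boundaries, mixed elements."""
    pos = rng.uniform(0.0, 4.0, (10, 3))
    z = rng.choice([1, 6, 7, 8, 16], 10)
    return ParticleSystem(pos, z)


@pytest.fixture
def charged_system(rng):
    pos = rng.uniform(0.0, 4.0, (8, 3))
    z = rng.choice([1, 6, 7, 8, 16], 8)
    q = rng.normal(0.0, 0.2, 8)
    q -= q.mean()
    return ParticleSystem(pos, z, charges=q)


def random_box(kind: str, rng) -> SimulationBox | None:
    if kind == "open":
        return None
    if kind == "rectangular":
        return SimulationBox(np.diag(rng.uniform(6.0, 12.0, 3)))
    ax, by, cz = rng.uniform(6.0, 12.0, 3)
    lat = np.array(
        [
            [ax, 0.0, 0.0],
            [rng.uniform(-ax / 2, ax / 2), by, 0.0],
            [rng.uniform(-ax / 2, ax / 2), rng.uniform(-by / 2, by / 2), cz],
        ]
    )
    return SimulationBox(lat)


def random_system(rng, n=None, n_batches=1, box_kind="open", charges=False):
    n = int(n if n is not None else rng.integers(2, 60))
    box = random_box(box_kind, rng)
    # open boxes scale with n^(1/3) so systems stay dense enough to have edges
    span = 1.0 + 2.5 * n ** (1 / 3) if box is None else np.diag(box.lattice).max()
    pos = rng.uniform(-2.0, span, (n, 3))
    batch = np.sort(rng.integers(0, n_batches, n))
    _, batch = np.unique(batch, return_inverse=True)
    z = rng.choice([1, 6, 7, 8, 16], n)
    q = None
    if charges:
        q = rng.normal(0.0, 0.2, n)
        q -= q.mean()
    return ParticleSystem(pos, z, batch=batch, charges=q, box=box)


def small_rep_config(model: str, num_layers: int = 2, cutoff: float = 3.0,
                     vector_cutoff: bool = True) -> RepresentationConfig:
    return RepresentationConfig(
        model=model,
        embedding_dimension=16,
        num_layers=num_layers,
        radial=RadialConfig(cutoff=cutoff, num_rbf=8),
        max_z=20,
        vector_cutoff=vector_cutoff,
    )


def random_orthogonal(rng, improper: bool = False) -> np.ndarray:
    """Haar-random rotation, optionally composed with a reflection."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    if improper:
        q = -q
    return q
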