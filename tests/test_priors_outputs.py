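"""Output head reduction and the four physical priors."""

import numpy as np
import pytest

from mlpot import autodiff as ad
from mlpot.geometry import ParticleSystem, brute_force_neighbors
from mlpot.nn import Module
from mlpot.outputs import OutputConfig, OutputHead, reduce_per_sample
from mlpot.priors import (
    AtomrefPrior,
    BasePrior,
    CoulombPrior,
    D2Prior,
    PriorConfigurationError,
    ZBLPrior,
    apply_priors,
    load_d2_table,
)
from mlpot.representations import prepare_edges
from mlpot.units import COULOMB_CONSTANT_EV

from conftest import random_orthogonal

RC = 5.0


def edges_for(system, cutoff=RC, capacity=None):
    nl = brute_force_neighbors(system, cutoff, capacity=capacity)
    pt = ad.Tensor(system.positions, requires_grad=True)
    return prepare_edges(pt, nl), pt


def pair_system(r, z=(1, 1), q=None):
    return ParticleSystem(
        [[0.0, 0, 0], [r, 0, 0]], list(z), charges=q
    )


def prior_energy(prior, system, cutoff=RC):
    edges, _ = edges_for(system, cutoff)
    zero = ad.constant(np.zeros(system.n_batches))
    return prior.sample_level(zero, system, edges, system.n_batches).data


class TestOutputHead:
    def test_zero_features_zero_biases_give_zero(self, rng):
        head = OutputHead(8, OutputConfig(hidden_channels=4), rng)
        for layer in head.mlp.layers:
            layer.bias.data[:] = 0.0
        out = head(ad.constant(np.zeros((5, 8))))
        assert np.all(out.data == 0.0)

    def test_single_batch_sum_is_plain_sum(self, rng):
        head = OutputHead(8, OutputConfig(), rng)
        per_atom = head(ad.constant(rng.normal(size=(6, 8))))
        total = reduce_per_sample(per_atom, np.zeros(6, int), 1).data
        assert total[0] == pytest.approx(per_atom.data.sum())

    def test_batch_split_partitions_the_sum(self, rng):
        per_atom = ad.constant(rng.normal(size=7))
        joint = reduce_per_sample(per_atom, np.zeros(7, int), 1).data
        split = reduce_per_sample(
            per_atom, np.array([0, 0, 0, 1, 1, 1, 1]), 2
        ).data
        assert split.sum() == pytest.approx(joint[0])

    def test_mean_reduction(self, rng):
        per_atom = ad.constant(np.array([2.0, 4.0, 9.0]))
        got = reduce_per_sample(per_atom, np.array([0, 0, 1]), 2, "mean").data
        np.testing.assert_allclose(got, [3.0, 9.0])


class TestAtomref:
    def test_table_lookup_arithmetic(self):
        table = np.zeros(10)
        table[6] = -1000.0
        prior = AtomrefPrior(table)
        s = ParticleSystem([[0.0, 0, 0]], [6])
        edges, _ = edges_for(s)
        out = prior.atom_level(ad.constant(np.array([0.1])), s, edges)
        assert out.data[0] == pytest.approx(-999.9)

    def test_zero_table_is_identity(self, rng, small_system):
        prior = AtomrefPrior(np.zeros(120))
        edges, _ = edges_for(small_system)
        x = ad.constant(rng.normal(size=small_system.n_atoms))
        np.testing.assert_array_equal(
            prior.atom_level(x, small_system, edges).data, x.data
        )

    def test_missing_element_raises(self):
        prior = AtomrefPrior(np.zeros(5))
        s = ParticleSystem([[0.0, 0, 0]], [8])
        edges, _ = edges_for(s)
        with pytest.raises(PriorConfigurationError):
            prior.atom_level(ad.constant(np.zeros(1)), s, edges)


class TestCoulomb:
    def test_pair_beyond_switch_is_bare_coulomb(self):
        s = pair_system(5.0, q=[+1.0, -1.0])
        prior = CoulombPrior(switching_distance=2.0, k=1.0)
        assert prior_energy(prior, s, cutoff=6.0)[0] == pytest.approx(-0.2)

    def test_switch_kills_short_range_singularity(self):
        prior = CoulombPrior(switching_distance=2.0, k=1.0)
        energies = [
            prior_energy(prior, pair_system(r, q=[1.0, 1.0]))[0]
            for r in (1e-3, 1e-2, 0.1)
        ]
        assert abs(energies[0]) < abs(energies[1]) < abs(energies[2])
        assert abs(energies[0]) < 1e-2

    def test_three_charges_sum_pairwise(self, rng):
        pos = rng.uniform(0, 3, (3, 3))
        q = np.array([0.5, -0.3, -0.2])
        s = ParticleSystem(pos, [1, 1, 1], charges=q)
        prior = CoulombPrior(switching_distance=1.0, k=COULOMB_CONSTANT_EV)
        expected = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.linalg.norm(pos[j] - pos[i])
                sw = 1.0 if r >= 1.0 else 0.5 * (1 - np.cos(np.pi * r))
                expected += sw * COULOMB_CONSTANT_EV * q[i] * q[j] / r
        assert prior_energy(prior, s)[0] == pytest.approx(expected, rel=1e-12)

    def test_missing_charges_raise_named_error(self, small_system):
        prior = CoulombPrior(switching_distance=1.0)
        edges, _ = edges_for(small_system)
        with pytest.raises(PriorConfigurationError, match="coulomb"):
            prior.sample_level(
                ad.constant(np.zeros(1)), small_system, edges, 1
            )


class TestZBL:
    def setup_method(self):
        self.prior = ZBLPrior(cutoff=RC)

    def test_screening_function_at_zero_is_coefficient_sum(self):
        f0 = self.prior.screening_function(ad.constant(np.zeros(1))).data[0]
        assert f0 == pytest.approx(self.prior.coefficients.sum(), abs=0)
        assert f0 == pytest.approx(1.0, abs=1e-4)

    def test_energy_strictly_decreasing_on_grid(self):
        rs = np.linspace(0.05, RC - 1e-6, 300)
        es = np.array(
            [prior_energy(self.prior, pair_system(r, (6, 8)))[0] for r in rs]
        )
        assert np.all(np.diff(es) < 0)
        assert np.all(es > 0)

    def test_pair_beyond_cutoff_contributes_zero(self):
        prior = ZBLPrior(cutoff=2.0)
        assert prior_energy(prior, pair_system(3.0, (6, 6)), cutoff=5.0)[0] == 0.0


class TestD2:
    def test_c6_geometric_combination(self):
        assert np.sqrt(4.0 * 9.0) == pytest.approx(6.0)
        table = load_d2_table()
        prior = D2Prior(c6_conversion=1.0, table={6: (4.0, 1.0), 8: (9.0, 1.0)})
        # far pair, damping ~ 1: E = -C6_ij / r^6
        r = 10.0
        e = prior_energy(prior, pair_system(r, (6, 8)), cutoff=12.0)[0]
        assert e == pytest.approx(-6.0 / r**6, rel=1e-6)
        assert 1 in table and 16 in table  # bundled coverage of fixtures set

    def test_damping_half_at_vdw_radius_sum(self):
        prior = D2Prior(c6_conversion=1.0, table={1: (1.0, 1.1)})
        r = 2.2  # R_ij = 1.1 + 1.1
        e = prior_energy(prior, pair_system(r, (1, 1)), cutoff=5.0)[0]
        assert e == pytest.approx(-0.5 * 1.0 / r**6, rel=1e-12)

    def test_missing_element_raises_with_name(self):
        prior = D2Prior()
        s = pair_system(1.0, (1, 40))
        edges, _ = edges_for(s)
        with pytest.raises(PriorConfigurationError, match="40"):
            prior.sample_level(ad.constant(np.zeros(1)), s, edges, 1)


class TestComposition:
    def test_empty_prior_list_is_identity(self, small_system):
        edges, _ = edges_for(small_system)
        per_atom = ad.constant(np.arange(10, dtype=float))
        pa, ps = apply_priors(per_atom, small_system, edges, 1, [])
        np.testing.assert_array_equal(pa.data, per_atom.data)
        assert ps.data[0] == pytest.approx(per_atom.data.sum())

    def test_zbl_plus_coulomb_additivity(self, charged_system):
        edges, _ = edges_for(charged_system)
        zero = ad.constant(np.zeros(charged_system.n_atoms))
        zbl = ZBLPrior(cutoff=RC)
        cou = CoulombPrior(switching_distance=1.0)
        _, together = apply_priors(zero, charged_system, edges, 1, [zbl, cou])
        e_zbl = prior_energy(zbl, charged_system)
        e_cou = prior_energy(cou, charged_system)
        np.testing.assert_allclose(together.data, e_zbl + e_cou, rtol=1e-12)

    def test_custom_prior_composes_like_builtins(self, small_system):
        class PerAtomShift(BasePrior):
            def atom_level(self, per_atom, system, edges):
                return per_atom + 2.5

        edges, _ = edges_for(small_system)
        zero = ad.constant(np.zeros(small_system.n_atoms))
        _, ps = apply_priors(zero, small_system, edges, 1, [PerAtomShift()])
        assert ps.data[0] == pytest.approx(2.5 * small_system.n_atoms)

    def test_half_list_counts_each_pair_once(self):
        # two atoms, unit charges: bare Coulomb must appear exactly once
        s = pair_system(4.0, q=[1.0, 1.0])
        prior = CoulombPrior(switching_distance=1.0, k=1.0)
        assert prior_energy(prior, s)[0] == pytest.approx(0.25)


class TestPriorPhysics:
    @pytest.mark.parametrize(
        "make",
        [
            lambda: ZBLPrior(cutoff=RC),
            lambda: D2Prior(),
            lambda: CoulombPrior(switching_distance=1.5),
        ],
        ids=["zbl", "d2", "coulomb"],
    )
    def test_invariance_under_o3_and_translation(self, make, charged_system, rng):
        prior = make()
        e0 = prior_energy(prior, charged_system)
        q = random_orthogonal(rng, improper=True)
        moved = ParticleSystem(
            charged_system.positions @ q.T + 3.0,
            charged_system.atomic_numbers,
            charges=charged_system.charges,
        )
        e1 = prior_energy(prior, moved)
        np.testing.assert_allclose(e1, e0, rtol=1e-10)

    @pytest.mark.parametrize(
        "make",
        [
            lambda: ZBLPrior(cutoff=RC),
            lambda: D2Prior(),
            lambda: CoulombPrior(switching_distance=1.5),
        ],
        ids=["zbl", "d2", "coulomb"],
    )
    def test_forces_match_finite_differences(self, make, charged_system):
        prior = make()

        def total(pos):
            s = ParticleSystem(
                pos, charged_system.atomic_numbers, charges=charged_system.charges
            )
            return prior_energy(prior, s)[0]

        edges, pt = edges_for(charged_system)
        zero = ad.constant(np.zeros(1))
        e = prior.sample_level(zero, charged_system, edges, 1)
        (g,) = ad.grad(ad.tsum(e), pt)
        h = 1e-5
        fd = np.zeros_like(charged_system.positions)
        for i in range(charged_system.n_atoms):
            for k in range(3):
                p = charged_system.positions.copy()
                p[i, k] += h
                up = total(p)
                p[i, k] -= 2 * h
                dn = total(p)
                fd[i, k] = (up - dn) / (2 * h)
        scale = np.max(np.abs(fd)) + 1e-12
        np.testing.assert_allclose(g.data / scale, fd / scale, atol=1e-5)
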