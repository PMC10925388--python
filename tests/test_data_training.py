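"""Dataset round-trips, splits, losses, EMA, training loop, checkpoints."""

import numpy as np
import pytest

from mlpot.data import (
    ConformerRecord,
    SplitSpec,
    load_custom_numpy,
    load_hdf5,
    load_splits,
    make_splits,
    read_xyz,
    save_splits,
    write_hdf5,
    write_xyz,
)
from mlpot.featurization import RadialConfig
from mlpot.fixtures import (
    make_atomref_dataset,
    make_dimer_dataset,
    write_custom_numpy,
)
from mlpot.model import AssembledModel, Prediction
from mlpot.outputs import OutputConfig
from mlpot.priors import AtomrefPrior
from mlpot.representations import RepresentationConfig
from mlpot import autodiff as ad
from mlpot.training import (
    Adam,
    EMAState,
    LossWeights,
    TrainingConfig,
    collate,
    ema_update,
    load_model,
    loss_tensors,
    save_checkpoint,
    train_loop,
    validation_metrics,
)

from conftest import small_rep_config


@pytest.fixture
def dimer_ds():
    return make_dimer_dataset(n_samples=24, seed=5)


class TestCustomNumpyLayout:
    def test_round_trip_identity(self, dimer_ds, tmp_path):
        globs = write_custom_numpy(dimer_ds, str(tmp_path))
        loaded = load_custom_numpy(**globs)
        assert len(loaded) == len(dimer_ds)
        for a, b in zip(dimer_ds.records, loaded.records):
            np.testing.assert_array_equal(a.z, b.z)
            np.testing.assert_array_equal(a.pos, b.pos)
            assert a.y == b.y
            np.testing.assert_array_equal(a.neg_dy, b.neg_dy)

    def test_forces_optional(self, tmp_path):
        ds, _ = make_atomref_dataset(n_samples=10, seed=0)
        for r in ds.records:
            r.neg_dy = None
        globs = write_custom_numpy(ds, str(tmp_path))
        loaded = load_custom_numpy(
            globs["coordglob"], globs["embedglob"], globs["energyglob"]
        )
        assert len(loaded) == 10 and not loaded.has_forces

    def test_conformer_count_mismatch_names_both_files(self, dimer_ds, tmp_path):
        globs = write_custom_numpy(dimer_ds, str(tmp_path))
        energy_files = sorted(tmp_path.glob("*.energy.npy"))
        np.save(energy_files[0], np.zeros((3, 1)))
        with pytest.raises(ValueError, match="mismatch"):
            load_custom_numpy(**globs)


class TestHDF5Layout:
    def test_round_trip_identity_mixed_sizes(self, tmp_path):
        ds = make_dimer_dataset(n_samples=6, seed=1)
        big, _ = make_atomref_dataset(n_samples=6, seed=2)
        for r in big.records:
            ds.append(r)
        path = str(tmp_path / "ds.h5")
        write_hdf5(ds, path)
        loaded = load_hdf5(path)
        assert len(loaded) == 12
        got = sorted(loaded.records, key=lambda r: r.y)
        want = sorted(ds.records, key=lambda r: r.y)
        for a, b in zip(want, got):
            np.testing.assert_array_equal(a.pos, b.pos)
            np.testing.assert_array_equal(a.z, b.z)

    def test_empty_file_gives_empty_dataset(self, tmp_path):
        import h5py

        path = str(tmp_path / "empty.h5")
        h5py.File(path, "w").close()
        assert len(load_hdf5(path)) == 0

    def test_lazy_mode_matches_in_memory(self, dimer_ds, tmp_path):
        path = str(tmp_path / "ds.h5")
        write_hdf5(dimer_ds, path)
        eager = load_hdf5(path, in_memory=True)
        lazy = load_hdf5(path, in_memory=False)
        assert len(lazy) == len(eager)
        np.testing.assert_array_equal(lazy[3].pos, eager[3].pos)

    def test_malformed_group_names_path(self, tmp_path):
        import h5py

        path = str(tmp_path / "bad.h5")
        with h5py.File(path, "w") as f:
            f.create_group("mol_0").create_dataset("types", data=[1, 1])
        with pytest.raises(ValueError, match="mol_0"):
            load_hdf5(path)


class TestSplits:
    def test_disjoint_cover(self):
        tr, va, te = make_splits(10, SplitSpec(6, 2, 2, seed=0))
        assert sorted(np.concatenate([tr, va, te])) == list(range(10))

    def test_seed_determinism_and_persistence(self, tmp_path):
        a = make_splits(100, SplitSpec(0.8, 0.1, 0.1, seed=7))
        b = make_splits(100, SplitSpec(0.8, 0.1, 0.1, seed=7))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        path = str(tmp_path / "splits.npz")
        save_splits(path, *a)
        for x, y in zip(load_splits(path), a):
            np.testing.assert_array_equal(x, y)
        # indices never leak between sets across the round-trip
        tr, va, te = load_splits(path)
        assert not (set(tr) & set(va)) and not (set(tr) & set(te))

    def test_oversubscription_rejected(self):
        with pytest.raises(ValueError):
            make_splits(10, SplitSpec(8, 2, 2))


class TestLossAndMetrics:
    def test_perfect_prediction_gives_zero(self):
        y = ad.constant(np.array([1.0, 2.0]))
        loss = loss_tensors(y, None, y.data, None, LossWeights(1.0, 0.0))
        assert loss.item() == 0.0

    def test_energy_mse_value(self):
        y = ad.constant(np.array([2.0]))
        loss = loss_tensors(y, None, np.array([0.0]), None, LossWeights(1.0, 0.0))
        assert loss.item() == pytest.approx(4.0)

    def test_weighted_sum_of_terms(self, rng):
        y = ad.constant(rng.normal(size=4))
        f = ad.constant(rng.normal(size=(6, 3)))
        yt, ft = rng.normal(size=4), rng.normal(size=(6, 3))
        e_only = loss_tensors(y, f, yt, ft, LossWeights(1.0, 0.0)).item()
        f_only = loss_tensors(y, f, yt, ft, LossWeights(0.0, 1.0)).item()
        both = loss_tensors(y, f, yt, ft, LossWeights(0.5, 0.5)).item()
        assert both == pytest.approx(0.5 * (e_only + f_only))

    def test_force_loss_without_forces_rejected(self):
        y = ad.constant(np.zeros(2))
        with pytest.raises(ValueError):
            loss_tensors(y, None, np.zeros(2), None, LossWeights(1.0, 1.0))

    def test_validation_metrics_offset(self):
        pred = Prediction(y=np.array([1.0, 2.0]), neg_dy=np.zeros((2, 3)))
        m = validation_metrics(pred, np.array([0.5, 1.5]), np.zeros((2, 3)))
        assert m["l1_energy"] == pytest.approx(0.5)
        assert m["mse_energy"] == pytest.approx(0.25)
        assert m["l1_force"] == 0.0 and m["mse_force"] == 0.0

    def test_metrics_permutation_invariant(self, rng):
        y, yt = rng.normal(size=8), rng.normal(size=8)
        perm = rng.permutation(8)
        a = validation_metrics(Prediction(y=y), yt)
        b = validation_metrics(Prediction(y=y[perm]), yt[perm])
        assert a == pytest.approx(b)


class TestEMA:
    def test_alpha_one_tracks_raw(self):
        s = EMAState(alpha=1.0)
        for v in (3.0, -1.0, 7.0):
            s = ema_update(s, v)
            assert s.value == v

    def test_midpoint_update(self):
        s = EMAState(alpha=0.5, value=2.0)
        assert ema_update(s, 4.0).value == pytest.approx(3.0)

    def test_constant_stream_fixed_point(self):
        s = EMAState(alpha=0.3)
        for _ in range(10):
            s = ema_update(s, 5.0)
        assert s.value == pytest.approx(5.0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            EMAState(alpha=0.0)


def tiny_model(priors=None, derivative=True, seed=0):
    return AssembledModel(
        small_rep_config("graph_network", num_layers=1, cutoff=4.5),
        OutputConfig(hidden_channels=8),
        priors or [],
        derivative=derivative,
        seed=seed,
    )


class TestTrainingLoop:
    def test_gradients_are_finite_and_nonzero(self, dimer_ds):
        model = tiny_model()
        system, y_t, f_t = collate(dimer_ds.records[:8])
        y, positions = model.forward_tensors(system)
        (gpos,) = ad.grad(ad.tsum(y), positions, create_graph=True)
        loss = loss_tensors(
            y, ad.mul(gpos, -1.0), y_t, f_t, LossWeights(1.0, 0.5)
        )
        grads = ad.grad(loss, model.trainable_parameters())
        total = sum(np.abs(g.data).sum() for g in grads)
        assert np.isfinite(total) and total > 0.0

    def test_short_force_training_runs_and_improves(self, dimer_ds):
        model = tiny_model()
        splits = make_splits(len(dimer_ds), SplitSpec(16, 4, 4, seed=0))
        cfg = TrainingConfig(
            epochs=10, batch_size=8, learning_rate=1e-2,
            weights=LossWeights(1.0, 0.2), seed=0,
        )
        res = train_loop(model, dimer_ds, splits, cfg)
        hist = res["history"]
        assert hist[-1]["val_loss"] < hist[0]["val_loss"]

    def test_checkpoint_resume_reproduces_run(self, dimer_ds, tmp_path):
        splits = make_splits(len(dimer_ds), SplitSpec(16, 4, 4, seed=0))
        cfg_full = TrainingConfig(epochs=6, batch_size=8, seed=3)
        m_full = tiny_model(seed=1)
        full = train_loop(m_full, dimer_ds, splits, cfg_full)

        cfg_half = TrainingConfig(epochs=3, batch_size=8, seed=3)
        m_half = tiny_model(seed=1)
        ckpt = str(tmp_path / "ck.npz")
        train_loop(m_half, dimer_ds, splits, cfg_half, checkpoint_path=ckpt)
        m_resume = tiny_model(seed=1)
        resumed = train_loop(
            m_resume, dimer_ds, splits, cfg_full, resume_from=ckpt
        )
        for a, b in zip(full["history"], resumed["history"]):
            assert a["val_loss"] == pytest.approx(b["val_loss"], rel=1e-12)
        np.testing.assert_array_equal(
            np.concatenate([p.data.ravel() for p in m_full.parameters()]),
            np.concatenate([p.data.ravel() for p in m_resume.parameters()]),
        )

    def test_atomref_recovery_end_to_end(self):
        """A frozen-zero model plus learnable atomref recovers the offsets."""
        ds, mu = make_atomref_dataset(n_samples=200, noise_sd=0.01, seed=1)
        prior = AtomrefPrior(np.zeros(21), trainable=True)
        model = tiny_model(priors=[prior], derivative=False)
        for p in model.representation.parameters():
            p.requires_grad = False
        for p in model.head.parameters():
            p.requires_grad = False
            p.data[:] = 0.0
        splits = make_splits(len(ds), SplitSpec(160, 20, 20, seed=0))
        cfg = TrainingConfig(epochs=50, batch_size=50, learning_rate=0.2, seed=0)
        train_loop(model, ds, splits, cfg)
        err = max(abs(prior.table.data[z] - mu[z]) for z in mu)
        assert err < 0.05

    def test_nonfinite_loss_aborts_with_location(self, dimer_ds):
        model = tiny_model()
        splits = make_splits(len(dimer_ds), SplitSpec(16, 4, 4, seed=0))
        cfg = TrainingConfig(epochs=6, batch_size=8, learning_rate=1e200, seed=0)
        with pytest.raises(FloatingPointError, match="epoch"), np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                train_loop(model, dimer_ds, splits, cfg)


class TestCheckpoints:
    def test_round_trip_bit_identical_predictions(self, tmp_path, charged_system):
        model = tiny_model(priors=[AtomrefPrior(np.zeros(21), trainable=True)])
        path = str(tmp_path / "model.npz")
        save_checkpoint(path, model)
        loaded = load_model(path)
        a = model.predict(charged_system)
        b = loaded.predict(charged_system)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.neg_dy, b.neg_dy)

    def test_derivative_override_at_load(self, tmp_path, charged_system):
        model = tiny_model(derivative=False)
        path = str(tmp_path / "model.npz")
        save_checkpoint(path, model)
        loaded = load_model(path, derivative=True)
        assert loaded.predict(charged_system).neg_dy is not None

    def test_corrupt_file_raises_cleanly(self, tmp_path):
        path = tmp_path / "junk.npz"
        path.write_bytes(b"not a checkpoint")
        with pytest.raises(ValueError, match="cannot load"):
            load_model(str(path))


class TestXYZ:
    def test_round_trip_with_varying_atom_counts(self, tmp_path):
        structs = [
            (np.array([6, 1, 1]), np.random.default_rng(0).normal(size=(3, 3))),
            (np.array([8]), np.zeros((1, 3))),
        ]
        path = str(tmp_path / "s.xyz")
        write_xyz(path, structs)
        loaded = read_xyz(path)
        assert len(loaded) == 2
        for (z0, p0), (z1, p1) in zip(structs, loaded):
            np.testing.assert_array_equal(z0, z1)
            np.testing.assert_allclose(p0, p1, atol=1e-9)

    def test_unknown_symbol_rejected(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("1\n\nXx 0 0 0\n")
        with pytest.raises(ValueError, match="Xx"):
            read_xyz(str(path))
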