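"""Splitting, augmentation, metrics, checkpointing, and short training runs."""

import numpy as np
import pytest

from affinet.egnn import ModelConfig
from affinet.io_structures import InputError
from affinet.nnkit import Adam
from affinet.synthetic import OracleParams, make_complex, make_global_dataset
from affinet.training import (
    Checkpoint,
    Ensemble,
    TrainingConfig,
    augment_coordinates,
    compute_metrics,
    evaluate,
    kfold_indices,
    predict_totals,
    stratified_split,
    train_direct,
    train_kfold_ensemble,
    transfer_learn,
)

TINY_CFG = ModelConfig(n_s=8, n_f=4, n_passes=2, n_hidden=16, readout_hidden=16)


def tiny_dataset(n=6, seed=0):
    ds = make_global_dataset(
        n, seed=seed, params=OracleParams(noise_sd=0.0),
        n_protein_range=(6, 10), n_ligand_range=(4, 7),
    )
    return ds


class TestStratifiedSplit:
    def test_hundred_labels_exact_eighty(self):
        labels = np.random.default_rng(0).normal(6, 1.5, size=100)
        train, test = stratified_split(labels, train_frac=0.8, seed=1)
        assert len(train) == 80 and len(test) == 20

    def test_ten_labels_eight_train(self):
        labels = np.arange(10.0)
        train, test = stratified_split(labels, train_frac=0.8, seed=0)
        assert len(train) == 8 and len(test) == 2

    def test_five_value_bins_split_within_bins(self):
        # 5 copies each of {4..8}: every bin contributes 4 train / 1 test
        labels = np.repeat([4.0, 5.0, 6.0, 7.0, 8.0], 5)
        train, test = stratified_split(labels, train_frac=0.8, seed=3)
        for v in (4.0, 5.0, 6.0, 7.0, 8.0):
            idx = np.flatnonzero(labels == v)
            assert len(np.intersect1d(train, idx)) == 4
            assert len(np.intersect1d(test, idx)) == 1

    def test_partition_exhaustive_disjoint(self):
        labels = np.random.default_rng(2).normal(size=37)
        train, test = stratified_split(labels, train_frac=0.7, seed=5)
        merged = np.concatenate([train, test])
        assert len(np.unique(merged)) == 37

    def test_fallback_below_bin_count_warns(self):
        with pytest.warns(UserWarning, match="plain split"):
            train, test = stratified_split([1.0, 2.0, 3.0], train_frac=0.67, seed=0)
        assert len(train) + len(test) == 3

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            stratified_split([1.0, 2.0], train_frac=1.5)


class TestAugmentation:
    def test_displacement_never_exceeds_radius(self):
        rng = np.random.default_rng(0)
        coords = np.zeros((50, 3))
        for _ in range(200):
            moved = augment_coordinates(coords, 0.1, rng)
            assert np.linalg.norm(moved, axis=-1).max() <= 0.1

    def test_radius_zero_identity(self):
        rng = np.random.default_rng(0)
        coords = np.random.default_rng(1).normal(size=(10, 3))
        assert np.array_equal(augment_coordinates(coords, 0.0, rng), coords)

    def test_mean_norm_matches_uniform_ball(self):
        # E||x|| = 3r/4 for uniform-in-ball; Monte-Carlo oracle at 1e5 draws
        rng = np.random.default_rng(42)
        norms = np.linalg.norm(
            augment_coordinates(np.zeros((100_000, 3)), 0.1, rng), axis=-1
        )
        assert norms.mean() == pytest.approx(0.075, abs=0.001)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            augment_coordinates(np.zeros((1, 3)), -0.1, np.random.default_rng(0))


class TestMetrics:
    def test_perfect_predictions(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmse == 0.0 and m.mue == 0.0 and m.r2 == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        m = compute_metrics([1.0, 2.0], [1.0, 4.0])
        assert m.mue == pytest.approx(1.0)
        assert m.rmse == pytest.approx(np.sqrt(2.0))

    def test_constant_offset_r2_one(self):
        labels = np.array([4.0, 5.0, 7.0])
        m = compute_metrics(labels + 0.7, labels)
        assert m.r2 == pytest.approx(1.0)
        assert m.mue == pytest.approx(0.7)

    def test_rmse_at_least_mue(self):
        rng = np.random.default_rng(0)
        m = compute_metrics(rng.normal(size=50), rng.normal(size=50))
        assert m.rmse >= m.mue >= 0.0

    def test_zero_variance_r2_zero_with_warning(self):
        with pytest.warns(UserWarning):
            m = compute_metrics([5.0, 5.0], [1.0, 2.0])
        assert m.r2 == 0.0


class TestTrainDirect:
    def test_determinism_bit_identical(self):
        ds = tiny_dataset()
        cfg = TrainingConfig(epochs=2, batch_size=3, seed=9, augment_radius=0.1)
        a = train_direct(ds, cfg, TINY_CFG)
        b = train_direct(ds, cfg, TINY_CFG)
        for k, p in a.all_params().items():
            assert np.array_equal(p.data, b.all_params()[k].data), k

    def test_shift_initialized_to_mean(self):
        ds = tiny_dataset()
        cfg = TrainingConfig(epochs=0, seed=0)
        ckpt = train_direct(ds, cfg, TINY_CFG)
        assert ckpt.readout.shift.data == pytest.approx(
            np.mean([cx.label for cx in ds])
        )

    def test_empty_dataset_rejected(self):
        with pytest.raises(InputError):
            train_direct([], TrainingConfig(), TINY_CFG)

    def test_unlabeled_rejected(self):
        ds = tiny_dataset()
        ds[0].label = None
        with pytest.raises(InputError):
            train_direct(ds, TrainingConfig(), TINY_CFG)

    def test_loss_decreases(self):
        ds = tiny_dataset(10)
        cfg = TrainingConfig(
            epochs=30, batch_size=10, lr=5e-3, warmup_steps=5,
            augment_radius=0.0, seed=0,
        )
        ckpt = train_direct(ds, cfg, TINY_CFG)
        assert np.mean(ckpt.loss_history[-5:]) < ckpt.loss_history[0]


class TestCheckpointIO:
    def test_save_load_round_trip(self, tmp_path):
        ds = tiny_dataset()
        ckpt = train_direct(ds, TrainingConfig(epochs=1, seed=0), TINY_CFG)
        path = tmp_path / "ckpt.npz"
        ckpt.save(path)
        back = Checkpoint.load(path)
        assert back.config_hash() == ckpt.config_hash()
        p1 = predict_totals(ckpt, ds)
        p2 = predict_totals(back, ds)
        assert np.array_equal(p1, p2)


class TestKFold:
    def test_fold_partition_property(self):
        folds = kfold_indices(23, 5, seed=0)
        merged = np.concatenate(folds)
        assert len(merged) == 23 and len(np.unique(merged)) == 23

    def test_default_ensemble_has_five_members(self):
        ds = tiny_dataset(10)
        cfg = TrainingConfig(epochs=1, batch_size=8, seed=0, augment_radius=0.0)
        ens = train_kfold_ensemble(ds, 5, cfg, TINY_CFG)
        assert len(ens.members) == 5
        assert sorted(m.fold_id for m in ens.members) == [0, 1, 2, 3, 4]

    def test_mean_of_identical_members_is_member(self):
        ds = tiny_dataset(6)
        ckpt = train_direct(ds, TrainingConfig(epochs=1, seed=0), TINY_CFG)
        ens = Ensemble(members=[ckpt, ckpt, ckpt])
        assert np.allclose(
            predict_totals(ens, ds), predict_totals(ckpt, ds), atol=1e-12
        )

    def test_k_larger_than_dataset_rejected(self):
        with pytest.raises(InputError):
            train_kfold_ensemble(tiny_dataset(4), 10, TrainingConfig(), TINY_CFG)

    def test_ensemble_spread_shapes(self):
        from affinet.training import ensemble_spread

        ds = tiny_dataset(6)
        a = train_direct(ds, TrainingConfig(epochs=1, seed=0), TINY_CFG)
        b = train_direct(ds, TrainingConfig(epochs=1, seed=1), TINY_CFG)
        mean, std = ensemble_spread(Ensemble(members=[a, b]), ds)
        assert mean.shape == std.shape == (6,)
        assert np.all(std >= 0)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_nan_loss_aborts_with_batch_ids(self):
        ds = tiny_dataset(4)
        # absurd learning rate drives activations to overflow within epochs
        cfg = TrainingConfig(
            epochs=50, batch_size=4, lr=1e18, warmup_steps=0,
            augment_radius=0.0, seed=0,
        )
        with pytest.raises(RuntimeError, match="batch ids"):
            train_direct(ds, cfg, TINY_CFG)


class TestTransferLearn:
    @pytest.fixture()
    def base(self):
        return train_direct(
            tiny_dataset(8, seed=1),
            TrainingConfig(epochs=2, batch_size=4, seed=0, augment_radius=0.0),
            TINY_CFG,
        )

    def test_zero_steps_only_shift_changes(self, base):
        local = tiny_dataset(5, seed=2)
        ckpt = transfer_learn(base, local, TrainingConfig(epochs=0, seed=1))
        base_params = base.all_params()
        for k, p in ckpt.all_params().items():
            if k.endswith("shift"):
                assert p.data != base_params[k].data
            else:
                assert np.array_equal(p.data, base_params[k].data), k
        # shift calibration: mean prediction equals the local label mean
        preds = predict_totals(ckpt, local)
        assert preds.mean() == pytest.approx(np.mean([c.label for c in local]))

    def test_nothing_frozen_after_one_step(self, base):
        local = tiny_dataset(5, seed=3)
        cfg = TrainingConfig(epochs=1, batch_size=5, seed=1, augment_radius=0.0)
        ckpt = transfer_learn(base, local, cfg)
        base_params = base.all_params()
        embed = [k for k in base_params if k.startswith("enc.embedding")]
        assert any(
            not np.array_equal(ckpt.all_params()[k].data, base_params[k].data)
            for k in embed
        )

    def test_momenta_start_at_zero(self):
        x_params = {"w": __import__("affinet.nnkit", fromlist=["Tensor"]).Tensor(
            np.ones(3), requires_grad=True
        )}
        opt = Adam(x_params, lr=1e-3, warmup_steps=10)
        assert all(np.all(m == 0) for m in opt.m.values())
        assert opt.step_count == 0

    def test_retain_shift_flag(self, base):
        local = tiny_dataset(5, seed=4)
        ckpt = transfer_learn(
            base, local, TrainingConfig(epochs=0, seed=0, retain_shift=True)
        )
        assert ckpt.readout.shift.data == pytest.approx(float(base.readout.shift.data))

    def test_mode_mismatch_rejected(self, base):
        with pytest.raises(ValueError):
            transfer_learn(base, tiny_dataset(4), TrainingConfig(mode="ligand_only"))


class TestEvaluate:
    def test_fresh_model_predicts_mean_everywhere(self):
        ds = tiny_dataset(6)
        ckpt = train_direct(ds, TrainingConfig(epochs=0, seed=0), TINY_CFG)
        preds = predict_totals(ckpt, ds)
        assert np.allclose(preds, np.mean([c.label for c in ds]), atol=1e-12)

    def test_evaluate_returns_metrics(self):
        ds = tiny_dataset(6)
        ckpt = train_direct(ds, TrainingConfig(epochs=1, seed=0), TINY_CFG)
        m = evaluate(ckpt, ds)
        assert m.n == 6 and m.rmse >= 0.0 and 0.0 <= m.r2 <= 1.0


class TestLigandOnlyMode:
    def test_trains_and_uses_fewer_edge_evaluations(self):
        ds = tiny_dataset(6)
        from affinet.readout import collate
        from affinet.training import prepare_graphs

        graphs = prepare_graphs(ds, TINY_CFG)
        full = collate(ds, graphs, "full")
        lig = collate(ds, graphs, "ligand_only")
        assert len(lig.edges) < len(full.edges)
        assert len(lig.pair_i) == 0
        cfg = TrainingConfig(epochs=2, batch_size=6, mode="ligand_only", seed=0)
        ckpt = train_direct(ds, cfg, TINY_CFG)
        assert ckpt.mode == "ligand_only"

    def test_augmentation_hurts_memorization(self):
        # heavy jitter makes a memorization task strictly harder
        ds = tiny_dataset(8)
        common = dict(epochs=40, batch_size=8, lr=5e-3, warmup_steps=5, seed=0)
        clean = train_direct(ds, TrainingConfig(augment_radius=0.0, **common), TINY_CFG)
        noisy = train_direct(ds, TrainingConfig(augment_radius=0.5, **common), TINY_CFG)
        assert np.mean(clean.loss_history[-8:]) < np.mean(noisy.loss_history[-8:])
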