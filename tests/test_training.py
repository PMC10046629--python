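"""Splits, normalization, losses and schedule contracts."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwbrain.msegnet import MSegNet, MSegNetConfig
from mwbrain.synthetic_data import LABELS, LabeledSample
from mwbrain.training import (
    NormalizationStats,
    PlateauController,
    TrainConfig,
    compute_stats,
    dice_loss,
    make_folds,
    train_model,
    zscore_normalize,
)


def dummy_dataset(n_per_class, size=8):
    """Minimal balanced dataset for split logic (content irrelevant)."""
    rng = np.random.default_rng(0)
    out = []
    for label in LABELS:
        for i in range(n_per_class):
            out.append(LabeledSample(
                image=rng.random((size, size, 3)).astype(np.float32),
                mask=np.zeros((size, size), dtype=np.uint8),
                label=label, sample_id=f"{label}_{i:03d}"))
    return out


class TestMakeFolds:
    def test_full_dataset_fold_counts(self):
        """300 images, k=5: per fold 60 test, 48 validation, 192 fitting."""
        folds = make_folds(dummy_dataset(100), k=5, seed=1)
        assert len(folds) == 5
        for f in folds:
            assert len(f.test_ids) == 60
            assert len(f.validation_ids) == 48
            assert len(f.train_ids) == 192
            assert not (set(f.test_ids) & set(f.validation_ids))
            assert not (set(f.test_ids) & set(f.train_ids))
            assert not (set(f.validation_ids) & set(f.train_ids))
            assert len(set(f.train_ids) | set(f.validation_ids)
                       | set(f.test_ids)) == 300

    def test_test_sets_partition_dataset(self):
        folds = make_folds(dummy_dataset(100), k=5, seed=1)
        all_test = [sid for f in folds for sid in f.test_ids]
        assert len(all_test) == 300
        assert len(set(all_test)) == 300

    def test_stratification_per_class(self):
        folds = make_folds(dummy_dataset(100), k=5, seed=2)
        for f in folds:
            for label in LABELS:
                assert sum(sid.startswith(label) for sid in f.test_ids) == 20
                assert sum(sid.startswith(label) for sid in f.validation_ids) == 16
                assert sum(sid.startswith(label) for sid in f.train_ids) == 64

    def test_seeded_determinism(self):
        ds = dummy_dataset(10)
        assert make_folds(ds, seed=7) == make_folds(ds, seed=7)
        assert make_folds(ds, seed=7) != make_folds(ds, seed=8)

    def test_indivisible_class_count_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            make_folds(dummy_dataset(7), k=5)

    def test_unbalanced_dataset_rejected(self):
        ds = dummy_dataset(10)[:-1]
        with pytest.raises(ValueError, match="balanced"):
            make_folds(ds, k=5)


class TestZScore:
    def test_own_stats_give_zero_mean_unit_std(self):
        rng = np.random.default_rng(3)
        ds = [LabeledSample(image=rng.random((8, 8, 3)).astype(np.float32) * 2,
                            mask=np.zeros((8, 8), np.uint8),
                            label="non_tumor", sample_id=f"s{i}")
              for i in range(20)]
        stats = compute_stats(ds)
        normed = zscore_normalize(np.stack([s.image for s in ds]), stats)
        assert np.abs(normed.mean(axis=(0, 1, 2))).max() < 1e-6
        assert np.abs(normed.std(axis=(0, 1, 2)) - 1).max() < 1e-5

    def test_identity_stats(self):
        stats = NormalizationStats(mean=(0, 0, 0), std=(1, 1, 1))
        x = np.random.default_rng(0).random((2, 4, 4, 3)).astype(np.float32)
        np.testing.assert_array_equal(zscore_normalize(x, stats), x)

    def test_constant_images_rejected(self):
        ds = [LabeledSample(image=np.full((8, 8, 3), 0.5, np.float32),
                            mask=np.zeros((8, 8), np.uint8),
                            label="non_tumor", sample_id="s")]
        with pytest.raises(ValueError, match="std"):
            compute_stats(ds)
        with pytest.raises(ValueError):
            NormalizationStats(mean=(0, 0, 0), std=(1, 0, 1))


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        m = np.zeros((32, 32))
        m[4:14, 4:14] = 1
        assert dice_loss(m, m) == pytest.approx(0.0, abs=0.005)

    def test_disjoint_masks(self):
        """Two disjoint 100-px masks: loss = 1 - eps/(200 + eps)."""
        p = np.zeros((64, 64))
        g = np.zeros((64, 64))
        p[:10, :10] = 1
        g[40:50, 40:50] = 1
        assert dice_loss(p, g) == pytest.approx(1 - 1 / 201, abs=1e-12)

    def test_half_overlap(self):
        p = np.zeros((256, 256))
        g = np.zeros((256, 256))
        p[0, :100] = 1
        g[0, 50:150] = 1
        assert dice_loss(p, g) == pytest.approx(0.5, abs=0.005)

    @given(overlap=st.integers(0, 100))
    @settings(deadline=None, max_examples=30)
    def test_monotone_in_overlap_for_fixed_areas(self, overlap):
        """More overlap at fixed areas never increases the loss."""
        def loss_at(k):
            p = np.zeros(300)
            g = np.zeros(300)
            p[:100] = 1
            g[100 - k:200 - k] = 1
            return dice_loss(p, g)

        if overlap < 100:
            assert loss_at(overlap + 1) <= loss_at(overlap) + 1e-12
        assert 0.0 <= loss_at(overlap) < 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPlateauController:
    def test_frozen_metric_decays_lr_then_stops(self):
        """Table-4 schedule: x0.2 after 10 stale epochs, stop after 15."""
        ctl = PlateauController(lr=5e-4, factor=0.2, plateau_patience=10,
                                stop_patience=15, mode="min")
        lr, stop = ctl.update(1.0)  # first epoch sets the best
        lrs, stops = [], []
        for _ in range(15):
            lr, stop = ctl.update(1.0)
            lrs.append(lr)
            stops.append(stop)
        assert lrs[8] == pytest.approx(5e-4)    # 9 stale epochs: unchanged
        assert lrs[9] == pytest.approx(1e-4)    # 10th stale epoch: 0.0005 * 0.2
        assert not any(stops[:14])
        assert stops[14]                        # 15th stale epoch stops

    def test_improvement_resets_counters(self):
        ctl = PlateauController(lr=1.0, factor=0.5, plateau_patience=2,
                                stop_patience=4, mode="max")
        for v in [0.1, 0.2, 0.2, 0.3]:
            lr, stop = ctl.update(v)
            assert lr == 1.0 and not stop


class TestTrainModel:
    def test_history_bookkeeping_and_best_so_far(self, small_dataset):
        """Best-so-far validation loss is non-increasing over epochs."""
        net = MSegNet(MSegNetConfig(initial_features=4, input_size=64),
                      rng=np.random.default_rng(1))
        cfg = TrainConfig.segmentation(max_epochs=3, seed=1)
        hist = train_model(net, small_dataset[:20], small_dataset[20:26],
                           cfg, task="segmentation")
        assert list(hist.columns) == ["epoch", "lr", "train_loss",
                                      "val_loss", "val_metric"]
        assert len(hist) <= 3
        best = hist["val_loss"].cummin()
        assert (best.diff().dropna() <= 1e-12).all()

    def test_empty_training_set_rejected(self, small_dataset):
        net = MSegNet(MSegNetConfig(initial_features=4, input_size=64),
                      rng=np.random.default_rng(1))
        with pytest.raises(ValueError, match="empty"):
            train_model(net, [], small_dataset[:4],
                        TrainConfig.segmentation(), task="segmentation")

    def test_yaml_roundtrip(self, tmp_path):
        cfg = TrainConfig.classification(max_epochs=7, seed=11)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert TrainConfig.from_yaml(tmp_path / "cfg.yaml") == cfg
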