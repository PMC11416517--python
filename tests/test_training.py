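"""Splitting, augmentation bookkeeping and the training loop contracts."""

import numpy as np
import pytest

from csvdnet.core import VolumeStack
from csvdnet.phantom import PhantomConfig
from csvdnet.training import (
    AugmentationPolicy,
    TrainConfig,
    augment_volume,
    balance_with_augmentation,
    make_split,
    policy_preset,
    run_kfold,
    train,
)
from csvdnet.nn import Network, bce_with_logits

from conftest import micro_network, reduced_stacks


def _stack(pid="p", label=1, n_real=20, depth=24, size=32, seed=0):
    rng = np.random.default_rng(seed)
    vox = np.zeros((depth, size, size, 1), dtype=np.float32)
    vox[:n_real] = rng.normal(size=(n_real, size, size, 1))
    return VolumeStack(voxels=vox, patient_id=pid, n_real_slices=n_real, label=label)


class TestMakeSplit:
    def test_study_cohort_45_patients(self):
        ids = [f"p{i}" for i in range(45)]
        labels = [1] * 30 + [0] * 15
        plan = make_split(ids, labels, seed=0)
        assert len(plan.test_ids) == 9
        pool = len(plan.train_ids) + len(plan.val_ids)
        assert pool == 36
        assert len(plan.val_ids) in (7, 8)
        assert len(plan.train_ids) in (28, 29)

    def test_stratified_test_preserves_2_to_1_ratio(self):
        ids = [f"p{i}" for i in range(45)]
        labels = [1] * 30 + [0] * 15
        plan = make_split(ids, labels, seed=1)
        test_labels = [labels[ids.index(p)] for p in plan.test_ids]
        assert sum(test_labels) == 6 and len(test_labels) - sum(test_labels) == 3

    @pytest.mark.parametrize("seed", range(25))
    def test_partition_property(self, seed):
        ids = [f"p{i}" for i in range(20)]
        labels = [1] * 12 + [0] * 8
        plan = make_split(ids, labels, seed=seed)
        union = set(plan.train_ids) | set(plan.val_ids) | set(plan.test_ids)
        assert union == set(ids)
        assert len(plan.train_ids) + len(plan.val_ids) + len(plan.test_ids) == 20

    def test_single_class_under_stratification_rejected(self):
        with pytest.raises(ValueError, match="class"):
            make_split(["a", "b", "c"], [1, 1, 1], seed=0)

    def test_deterministic_under_seed(self):
        ids = [f"p{i}" for i in range(30)]
        labels = [1] * 20 + [0] * 10
        assert make_split(ids, labels, seed=5) == make_split(ids, labels, seed=5)


class TestAugmentVolume:
    def test_shape_and_label_preserved(self):
        s = _stack()
        for op in ("translation", "shear", "rotation", "affine"):
            out = augment_volume(s, op, seed=3)
            assert out.shape == s.shape
            assert out.label == s.label
            assert out.source_id == s.patient_id

    def test_padding_tail_stays_zero(self):
        s = _stack(n_real=10)
        out = augment_volume(s, "rotation", seed=1)
        assert not out.voxels[10:].any()

    def test_translation_roundtrip_restores_interior(self):
        s = _stack(seed=4)
        from csvdnet.training import _inplane_matrix, AugmentationRanges
        from scipy import ndimage

        vol = s.voxels[..., 0]
        shifted = ndimage.shift(vol, (0, 5, 0), order=1, cval=0.0)
        back = ndimage.shift(shifted, (0, -5, 0), order=1, cval=0.0)
        interior = (slice(None), slice(6, -6), slice(6, -6))
        assert np.allclose(back[interior], vol[interior], atol=1e-6)

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            augment_volume(_stack(), "zoom", seed=0)
        with pytest.raises(ValueError, match="unknown"):
            AugmentationPolicy(ops_by_class={1: ("zoom",)})

    def test_deterministic_under_seed(self):
        s = _stack(seed=8)
        a = augment_volume(s, "affine", seed=11)
        b = augment_volume(s, "affine", seed=11)
        assert np.array_equal(a.voxels, b.voxels)


class TestBalanceWithAugmentation:
    def test_study_imbalance_becomes_60_60(self):
        stacks = [_stack(f"d{i}", 1, seed=i) for i in range(30)]
        stacks += [_stack(f"c{i}", 0, seed=100 + i) for i in range(15)]
        out = balance_with_augmentation(stacks, policy_preset("balance_shear"))
        labels = [s.label for s in out]
        assert labels.count(1) == 60 and labels.count(0) == 60

    def test_empty_policy_is_identity(self):
        stacks = [_stack("a", 1), _stack("b", 0)]
        out = balance_with_augmentation(
            stacks, AugmentationPolicy(ops_by_class={})
        )
        assert out == stacks

    def test_provenance_links_and_originals_retained(self):
        stacks = [_stack("a", 1), _stack("b", 0)]
        out = balance_with_augmentation(stacks, policy_preset("balance_rotation"))
        originals = [s for s in out if s.source_id is None]
        copies = [s for s in out if s.source_id is not None]
        assert originals == stacks
        assert all(c.source_id in ("a", "b") for c in copies)
        assert all(
            c.label == next(s.label for s in stacks if s.patient_id == c.source_id)
            for c in copies
        )

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            policy_preset("mixup")


class TestTrainLoop:
    def _toy_pool(self, n=4):
        rng = np.random.default_rng(0)
        pool = []
        for i in range(n):
            label = i % 2
            vox = np.zeros((6, 8, 8, 1), dtype=np.float32)
            vox[:4] = rng.normal(loc=2.0 * label, size=(4, 8, 8, 1))
            pool.append(VolumeStack(voxels=vox, patient_id=f"t{i}", n_real_slices=4,
                                    label=label))
        return pool

    def test_learning_rate_trace_non_increasing(self):
        _, net = micro_network(seed=1)
        hist = train(net, self._toy_pool(), config=TrainConfig(
            epochs=12, batch_size=2, plateau_patience=1, seed=0))
        lr = hist["lr"]
        assert all(b <= a for a, b in zip(lr, lr[1:]))

    def test_two_sample_memorization(self):
        """An unregularized micro model drives training loss below 0.01
        on a 2-sample task well within 500 epochs."""
        _, net = micro_network(seed=2, l2=0.0)
        pool = self._toy_pool(2)
        hist = train(net, pool, config=TrainConfig(
            epochs=150, batch_size=2, plateau_patience=1000, seed=0))
        assert min(hist["loss"]) < 0.01

    def test_identical_seed_identical_weights(self):
        pool = self._toy_pool()
        results = []
        for _ in range(2):
            _, net = micro_network(seed=3, dropout=0.2)
            train(net, pool, config=TrainConfig(epochs=3, batch_size=2, seed=9))
            results.append(net.state_arrays())
        for k in results[0]:
            assert np.array_equal(results[0][k], results[1][k])

    def test_empty_pool_rejected(self):
        _, net = micro_network()
        with pytest.raises(ValueError, match="empty"):
            train(net, [])

    def test_divergence_aborts_with_diagnostic(self):
        _, net = micro_network(seed=0)
        # poison a weight to force non-finite logits
        net.layers[-1].params["W"][:] = np.inf
        with pytest.raises(RuntimeError, match="diverged"):
            train(net, self._toy_pool(), config=TrainConfig(epochs=1, batch_size=2))


class TestRunKfold:
    @pytest.fixture(scope="class")
    def toy_cohort(self):
        rng = np.random.default_rng(5)
        cohort = []
        for i in range(24):
            label = int(i < 14)
            vox = np.zeros((6, 8, 8, 1), dtype=np.float32)
            vox[:5] = rng.normal(loc=1.5 * label, scale=1.0, size=(5, 8, 8, 1))
            cohort.append(VolumeStack(voxels=vox, patient_id=f"p{i}",
                                      n_real_slices=5, label=label))
        return cohort

    def _build(self):
        return micro_network(seed=7)[1]

    def test_fold_means_and_partitions(self, toy_cohort):
        res = run_kfold(
            toy_cohort, self._build, k=3, augmented=False,
            config=TrainConfig(epochs=2, batch_size=4, seed=1), seed=1,
        )
        assert res.k == 3 and len(res.fold_reports) == 3
        accs = [r.accuracy for r in res.fold_reports]
        assert res.mean_report.accuracy == pytest.approx(np.mean(accs))

    def test_augmented_group_mode_keeps_copies_out_of_other_folds(self, toy_cohort):
        from sklearn.model_selection import StratifiedGroupKFold
        from csvdnet.training import balance_with_augmentation, policy_preset

        pool = balance_with_augmentation(toy_cohort, policy_preset("balance_rotation", 3))
        groups = np.array([s.source_id or s.patient_id for s in pool])
        y = np.array([s.label for s in pool])
        for tr, va in StratifiedGroupKFold(n_splits=4).split(np.zeros(len(pool)), y, groups):
            assert not set(groups[tr]) & set(groups[va])

    def test_k_below_two_rejected(self, toy_cohort):
        with pytest.raises(ValueError):
            run_kfold(toy_cohort, self._build, k=1, augmented=False)
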