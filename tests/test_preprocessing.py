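"""Preprocessing stages: loading, sorting, filtering, resizing, padding."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csvdnet.core import NormalizationStats, SliceMeta, SliceRecord
from csvdnet.phantom import PhantomConfig, cohort_patients, generate_patient_series
from csvdnet.preprocessing import (
    build_stack,
    build_stack_from_records,
    compute_cohort_stats,
    compute_dataset_stats,
    discard_small,
    filter_axial_sequences,
    load_series,
    normalize,
    pad_stack,
    resize_slice,
    sort_by_instance,
)


def _rec(instance=1, plane="axial", sequence="T1W", size=128, value=None, pid="p"):
    px = np.full((size, size), float(instance) if value is None else value)
    return SliceRecord(SliceMeta(pid, instance, plane, sequence, size, size), px)


class TestLoadSeries:
    def test_count_matches_written_files(self, small_config, cohort_dir):
        pid, label, seed = cohort_patients(small_config)[0]
        source = generate_patient_series(small_config, pid, label, seed)
        assert len(load_series(cohort_dir / pid)) == len(source)

    def test_corrupt_file_skipped_with_log(self, cohort_dir, caplog, tmp_path):
        import shutil

        pdir = tmp_path / "patient"
        shutil.copytree(cohort_dir / "sub-0001", pdir)
        n_good = len(list(pdir.glob("*.dcm")))
        (pdir / "broken.dcm").write_bytes(b"\x00" * 100)  # truncated garbage
        with caplog.at_level(logging.WARNING):
            records = load_series(pdir)
        assert len(records) == n_good
        assert any("skipping" in r.message for r in caplog.records)

    def test_no_readable_files_is_an_error(self, tmp_path):
        (tmp_path / "junk.dcm").write_bytes(b"not dicom")
        with pytest.raises(ValueError, match="no readable"):
            load_series(tmp_path)

    def test_plane_and_sequence_recovered_from_dicom(self, small_config, cohort_dir):
        records = load_series(cohort_dir / "sub-0001")
        planes = {r.meta.plane for r in records}
        seqs = {r.meta.sequence for r in records}
        assert "axial" in planes and {"sagittal", "coronal"} <= planes
        assert {"T1W", "T2W", "FLAIR"} <= seqs


class TestSortByInstance:
    def test_sorts_ascending(self):
        recs = [_rec(3), _rec(1), _rec(2)]
        assert [r.meta.instance_number for r in sort_by_instance(recs)] == [1, 2, 3]

    def test_idempotent_on_sorted_input(self):
        recs = [_rec(1), _rec(2), _rec(3)]
        assert sort_by_instance(recs) == recs

    @given(st.randoms())
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, rnd):
        recs = [_rec(i) for i in range(1, 51)]
        shuffled = list(recs)
        rnd.shuffle(shuffled)
        assert sort_by_instance(shuffled) == sort_by_instance(recs)


class TestFilterAxialSequences:
    def test_keeps_only_axial_t1_t2_flair(self):
        recs = [_rec(i, "axial", "FLAIR") for i in range(1, 11)]
        recs += [_rec(i, "sagittal", "T1W") for i in range(1, 6)]
        assert len(filter_axial_sequences(recs)) == 10

    def test_all_coronal_is_an_error(self):
        with pytest.raises(ValueError, match="unusable"):
            filter_axial_sequences([_rec(1, "coronal"), _rec(2, "coronal")])

    def test_other_sequence_dropped_and_pixels_untouched(self):
        keep = _rec(1, "axial", "T2W", value=7.0)
        drop = _rec(2, "axial", "other")
        out = filter_axial_sequences([keep, drop])
        assert out == [keep]
        assert np.all(out[0].pixels == 7.0)


class TestDiscardAndResize:
    def test_size_64_discarded_256_512_retained(self):
        recs = [_rec(1, size=64), _rec(2, size=256), _rec(3, size=512)]
        kept = discard_small(recs)
        assert [r.meta.rows for r in kept] == [256, 512]

    def test_all_large_identity(self):
        recs = [_rec(i, size=256) for i in range(1, 4)]
        assert discard_small(recs) == recs

    def test_constructed_mixed_cohort_counts(self):
        recs = [_rec(i, size=64) for i in range(1, 38)]
        recs += [_rec(i, size=256) for i in range(38, 101)]
        assert len(discard_small(recs)) == 63

    def test_constant_slice_resizes_to_constant(self):
        out = resize_slice(_rec(1, size=256, value=3.25))
        assert out.pixels.shape == (128, 128)
        assert np.allclose(out.pixels, 3.25)

    def test_512_shrinks_to_128(self):
        assert resize_slice(_rec(1, size=512)).pixels.shape == (128, 128)

    def test_128_is_bitwise_identity(self):
        rec = _rec(1, size=128, value=1.5)
        out = resize_slice(rec)
        assert out.pixels is rec.pixels

    def test_upscaling_blocked(self):
        with pytest.raises(ValueError, match="upscale"):
            resize_slice(_rec(1, size=64))

    def test_area_resampling_preserves_mean(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(0, 100, (256, 256))
        rec = SliceRecord(SliceMeta("p", 1, "axial", "T1W", 256, 256), px)
        out = resize_slice(rec)
        assert out.pixels.mean() == pytest.approx(px.mean(), rel=1e-12)


class TestNormalization:
    def test_two_pixel_closed_form(self):
        recs = [_rec(1, size=64, value=0.0), _rec(2, size=64, value=2.0)]
        # restrict to 1 pixel each via direct construction
        a = SliceRecord(SliceMeta("p", 1, "axial", "T1W", 1, 1), np.array([[0.0]]))
        b = SliceRecord(SliceMeta("p", 2, "axial", "T1W", 1, 1), np.array([[2.0]]))
        stats = compute_dataset_stats([a, b])
        assert stats.mean == 1.0 and stats.std == 1.0  # population std

    def test_constant_cohort_is_an_error(self):
        recs = [_rec(1, value=5.0), _rec(2, value=5.0)]
        with pytest.raises(ValueError, match="constant"):
            compute_dataset_stats(recs)

    def test_seeded_standard_normal_sample(self):
        rng = np.random.default_rng(42)
        px = rng.standard_normal((40, 25))  # 1000 pixels
        rec = SliceRecord(SliceMeta("p", 1, "axial", "T1W", 40, 25 * 0 + 40), np.zeros((40, 40)))
        recs = [SliceRecord(SliceMeta("p", 1, "axial", "T1W", 40, 40),
                            rng.standard_normal((40, 40)))]
        stats = compute_dataset_stats(recs)
        assert abs(stats.mean) < 0.1
        assert 0.9 < stats.std < 1.1

    def test_normalize_fixed_points(self):
        stats = NormalizationStats(mean=10.0, std=2.0)
        at_mean = normalize(_rec(1, value=10.0), stats)
        assert np.all(at_mean.pixels == 0.0)
        plus_sigma = normalize(_rec(1, value=12.0), stats)
        assert np.all(plus_sigma.pixels == 1.0)

    def test_self_consistency_repooling_gives_unit_stats(self):
        rng = np.random.default_rng(1)
        recs = [
            SliceRecord(SliceMeta("p", i + 1, "axial", "T1W", 32, 32),
                        rng.uniform(0, 500, (32, 32)))
            for i in range(10)
        ]
        stats = compute_dataset_stats(recs)
        pooled = np.concatenate([normalize(r, stats).pixels.ravel() for r in recs])
        assert pooled.mean() == pytest.approx(0.0, abs=1e-9)
        assert pooled.std() == pytest.approx(1.0, rel=1e-6)


class TestPadStack:
    def _slices(self, n, size=128):
        return [np.full((size, size), i + 1.0) for i in range(n)]

    @pytest.mark.parametrize("n,zeros", [(23, 97), (115, 5), (120, 0)])
    def test_padding_counts(self, n, zeros):
        stack = pad_stack(self._slices(n), patient_id="p")
        assert stack.shape == (120, 128, 128, 1)
        assert stack.n_real_slices == n
        assert int(np.sum(~stack.voxels.any(axis=(1, 2, 3)))) >= zeros
        assert not stack.voxels[n:].any()
        # real region unaffected by padding
        assert np.all(stack.voxels[n - 1] == n)

    def test_too_many_slices_blocked(self):
        with pytest.raises(ValueError, match="truncation"):
            pad_stack(self._slices(121))

    def test_empty_input_blocked(self):
        with pytest.raises(ValueError):
            pad_stack([])


class TestBuildStack:
    def test_phantom_patient_yields_canonical_shape(self, small_config, cohort_dir):
        stats = compute_cohort_stats([cohort_dir / "sub-0001"])
        stack = build_stack(cohort_dir / "sub-0001", stats)
        assert stack.shape == (120, 128, 128, 1)

    def test_n_real_slices_matches_qualifying_count(self, small_config, cohort_dir):
        pid, label, seed = cohort_patients(small_config)[0]
        source = generate_patient_series(small_config, pid, label, seed)
        expected = sum(
            1 for r in source if r.meta.plane == "axial" and r.meta.rows >= 128
        )
        stats = compute_cohort_stats([cohort_dir / pid])
        stack = build_stack(cohort_dir / pid, stats)
        assert stack.n_real_slices == expected

    def test_on_disk_file_order_is_irrelevant(self, small_config, cohort_dir, tmp_path):
        import shutil

        src = cohort_dir / "sub-0001"
        shuffled = tmp_path / "shuffled"
        shuffled.mkdir()
        # copy under names that reverse the lexicographic read order
        files = sorted(src.glob("*.dcm"))
        for i, f in enumerate(files):
            shutil.copy(f, shuffled / f"{len(files) - i:03d}.dcm")
        stats = compute_cohort_stats([src])
        a = build_stack(src, stats)
        b = build_stack(shuffled, stats)
        assert np.array_equal(a.voxels, b.voxels)

    def test_end_to_end_determinism(self, small_config, cohort_dir):
        stats = compute_cohort_stats([cohort_dir / "sub-0002"])
        a = build_stack(cohort_dir / "sub-0002", stats)
        b = build_stack(cohort_dir / "sub-0002", stats)
        assert np.array_equal(a.voxels, b.voxels)

    def test_sequences_grouped_then_instance_ordered(self):
        cfg = PhantomConfig(
            slice_count_range=(9, 9), matrix_sizes=(64,), seed=3,
        )
        recs = generate_patient_series(cfg, "p", "control", seed=3)
        stats = compute_dataset_stats(
            [r for r in recs if r.meta.plane == "axial"]
        )
        stack = build_stack_from_records(recs, stats, min_size=32, target=32, depth=24)
        assert stack.n_real_slices == 9
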