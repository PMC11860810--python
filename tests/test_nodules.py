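"""Volumetry, type classification, Lung-RADS categorization, agreement."""
import numpy as np
import pytest

import thinslice as ts
from thinslice.nodules import (CATEGORIES, NoduleMeasurement, agreement,
                               classify_type, filter_by_volume,
                               image_quality, measure_volumes,
                               paired_agreement, segment_nodule)


class TestVolumetry:
    def test_unit_voxels(self):
        total = np.zeros((10, 10, 10), bool)
        total.flat[:100] = True
        m = measure_volumes(total, np.zeros_like(total), (1.0, 1.0, 1.0),
                            nodule_type="GGN")
        assert m.total_volume_mm3 == pytest.approx(100.0)
        assert m.solid_volume_mm3 == 0.0

    def test_anisotropic_voxel_volume(self):
        total = np.zeros((5, 5, 5), bool)
        total[:3, :3, :3] = True  # 27 voxels
        m = measure_volumes(total, total, (2.0, 0.5, 0.5),
                            nodule_type="solid")
        assert m.total_volume_mm3 == pytest.approx(13.5)

    def test_empty_total_mask_rejected(self):
        empty = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError):
            measure_volumes(empty, empty, (1, 1, 1))

    def test_solid_outside_total_rejected(self):
        total = np.zeros((3, 3, 3), bool)
        solid = np.zeros((3, 3, 3), bool)
        total[0, 0, 0] = True
        solid[1, 1, 1] = True
        with pytest.raises(ValueError):
            measure_volumes(total, solid, (1, 1, 1))


class TestClassifyType:
    def test_all_soft_tissue_is_solid(self):
        assert classify_type(np.full(100, 40.0)) == "solid"

    def test_all_ground_glass_is_ggn(self):
        assert classify_type(np.full(100, -650.0)) == "GGN"

    def test_intermediate_fraction_is_part_solid(self):
        hu = np.concatenate([np.full(30, 0.0), np.full(70, -650.0)])
        assert classify_type(hu, fractions=(0.1, 0.9)) == "part_solid"

    def test_fraction_boundaries(self):
        # exactly f_high solid fraction -> solid (closed-open intervals)
        hu = np.concatenate([np.full(90, 0.0), np.full(10, -650.0)])
        assert classify_type(hu, fractions=(0.1, 0.9)) == "solid"
        hu = np.concatenate([np.full(10, 0.0), np.full(90, -650.0)])
        assert classify_type(hu, fractions=(0.1, 0.9)) == "part_solid"


def oracle_category(m: NoduleMeasurement) -> str:
    """Independent if/elif transcription of the v2022 volume criteria."""
    if m.type == "solid":
        v = m.total_volume_mm3
        if v < 113.0:
            return "2"
        elif v < 268.0:
            return "3"
        elif v < 1767.0:
            return "4A"
        return "4B"
    if m.type == "part_solid":
        if m.total_volume_mm3 < 113.0:
            return "2"
        elif m.solid_volume_mm3 < 113.0:
            return "3"
        elif m.solid_volume_mm3 < 268.0:
            return "4A"
        return "4B"
    return "2" if m.total_volume_mm3 < 3351.0 else "3"


class TestCategorize:
    def test_below_lowest_cutpoint_is_category_2(self, lungrads_table):
        m = NoduleMeasurement(80.0, 80.0, "solid")
        assert ts.categorize(m, lungrads_table) == "2"

    def test_at_or_above_highest_cutpoint_is_4b(self, lungrads_table):
        assert ts.categorize(NoduleMeasurement(1767.0, 1767.0, "solid"),
                             lungrads_table) == "4B"
        assert ts.categorize(NoduleMeasurement(5000.0, 400.0, "part_solid"),
                             lungrads_table) == "4B"

    def test_exhaustive_grid_matches_interval_oracle(self, lungrads_table):
        grid = np.concatenate([np.arange(1.0, 4000.0, 7.3),
                               [112.999, 113.0, 267.999, 268.0,
                                1766.999, 1767.0, 3350.999, 3351.0]])
        for ntype in ("solid", "part_solid", "GGN"):
            for total in grid:
                solids = [0.0, total * 0.3, total * 0.6, total] \
                    if ntype == "part_solid" else \
                    ([total] if ntype == "solid" else [0.0])
                for solid in solids:
                    m = NoduleMeasurement(total, solid, ntype)
                    assert ts.categorize(m, lungrads_table) == \
                        oracle_category(m), (ntype, total, solid)

    def test_monotone_in_solid_volume(self, lungrads_table):
        order = {c: i for i, c in enumerate(CATEGORIES)}
        for total in (90.0, 150.0, 300.0, 2000.0):
            prev = -1
            for solid in np.linspace(0.0, total, 25):
                m = NoduleMeasurement(total, solid, "part_solid")
                cur = order[ts.categorize(m, lungrads_table)]
                assert cur >= prev
                prev = cur

    def test_table_version_pinned(self, lungrads_table):
        assert lungrads_table.version == "v2022-simplified"


class TestFilter:
    def test_boundary_inclusion_closed_interval(self):
        ms = [NoduleMeasurement(v, 0.0, "GGN")
              for v in (50.0, 80.0, 200.0, 350.0, 400.0)]
        kept = filter_by_volume(ms, 80.0, 350.0)
        assert [m.total_volume_mm3 for m in kept] == [80.0, 200.0, 350.0]

    def test_empty_input(self):
        assert filter_by_volume([]) == []

    def test_idempotent(self):
        ms = [NoduleMeasurement(v, 0.0, "GGN") for v in (80.0, 200.0)]
        once = filter_by_volume(ms)
        assert filter_by_volume(once) == once


class TestAgreement:
    def test_perfect_prediction(self):
        labels = ["2", "3", "4A", "4B", "2"]
        res = agreement(labels, labels)
        assert res.accuracy == 1.0
        assert np.trace(res.matrix.values) == 5

    def test_matrix_matches_tally_loop(self, rng):
        cats = list(CATEGORIES)
        pred = [cats[i] for i in rng.integers(0, 4, size=40)]
        ref = [cats[i] for i in rng.integers(0, 4, size=40)]
        res = agreement(pred, ref)
        for t in cats:
            for p in cats:
                expected = sum(1 for a, b in zip(pred, ref)
                               if a == p and b == t)
                assert res.matrix.loc[t, p] == expected
        assert res.matrix.values.sum() == 40

    def test_accuracy_invariant_under_relabeling(self, rng):
        cats = list(CATEGORIES)
        pred = [cats[i] for i in rng.integers(0, 4, size=30)]
        ref = [cats[i] for i in rng.integers(0, 4, size=30)]
        perm = {"2": "4B", "3": "4A", "4A": "3", "4B": "2"}
        a = agreement(pred, ref).accuracy
        b = agreement([perm[p] for p in pred],
                      [perm[t] for t in ref]).accuracy
        assert a == b

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            agreement(["2", "5"], ["2", "3"])

    def test_paired_partition_counts(self):
        ref = ["2"] * 6
        pred_a = ["2", "2", "3", "3", "2", "3"]
        pred_b = ["2", "3", "2", "3", "2", "2"]
        res = paired_agreement(pred_a, pred_b, ref)
        assert (res.only_a_correct, res.only_b_correct,
                res.both_incorrect, res.both_correct) == (1, 2, 1, 2)
        assert res.accuracy_a == pytest.approx(3 / 6)
        assert res.accuracy_b == pytest.approx(4 / 6)


class TestImageQuality:
    def test_identical_volumes(self, rng):
        v = rng.uniform(-1000, 400, (6, 16, 16))
        psnr, ssim = image_quality(v, v, data_range=4095.0)
        assert psnr == float("inf")
        assert ssim == pytest.approx(1.0)

    def test_constant_offset_closed_form(self, rng):
        v = rng.uniform(-500, 400, (6, 16, 16))
        c = 40.95
        psnr, _ = image_quality(v, v + c, data_range=4095.0)
        assert psnr == pytest.approx(20 * np.log10(4095.0 / c), rel=1e-9)

    def test_psnr_matches_reference_implementation(self, rng):
        from skimage.metrics import peak_signal_noise_ratio
        a = rng.uniform(0, 1, (4, 16, 16))
        b = rng.uniform(0, 1, (4, 16, 16))
        psnr, _ = image_quality(a, b, data_range=1.0)
        ref = peak_signal_noise_ratio(a, b, data_range=1.0)
        assert psnr == pytest.approx(ref, abs=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            image_quality(rng.random((3, 4, 4)), rng.random((3, 4, 5)))


class TestSegmentNodule:
    def test_recovers_sphere_from_clean_phantom(self):
        from thinslice.phantom import PhantomSpec, SyntheticNodule, \
            _lung_fields
        spec = PhantomSpec(shape=(48, 64, 64), spacing=(0.7, 0.7, 0.7),
                           noise_sd=0.0, seed=2)
        lc, _ = _lung_fields(spec)[0]
        spec.nodules = [SyntheticNodule(lc, "part_solid", 4.0, 3.0)]
        vol, masks, nodules = ts.generate_phantom(spec)
        total, solid = segment_nodule(vol, lc, 6.0)
        gt_total, gt_solid = masks[0]

        def dice(a, b):
            return 2 * (a & b).sum() / (a.sum() + b.sum())

        # threshold masks include a thin partial-volume shell, so require
        # high overlap rather than voxel-exact equality
        assert dice(total, gt_total) > 0.85
        assert dice(solid, gt_solid) > 0.85
        assert total[gt_solid].all()
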