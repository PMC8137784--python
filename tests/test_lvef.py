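"""LV segmentation and ejection-fraction quantification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from petlvef import (
    AcquisitionConfig,
    DoseModel,
    NegativeEjectionWarning,
    PlanarImage,
    RoiMask,
    VoxelGrid,
    activity_map,
    count_lvef,
    crop_center,
    first_pass_blood_concentration,
    lvef_from_measures,
    measure_lvef_pipeline,
    project_sum,
    segment_lv_2d,
    segment_lv_3d,
    simulate_frame,
    threshold_sweep,
)
from petlvef.grids import KIND_COUNTS, LABEL_LV, LABEL_MYOCARDIUM, LABEL_RV, SHORT_AXIS


class TestFormula:
    @pytest.mark.parametrize(
        "ed, es, expected",
        [(110.0, 62.0, 43.6), (100.0, 100.0, 0.0), (100.0, 0.0, 100.0), (3.0, 2.0, 33.3)],
    )
    def test_reference_cases(self, ed, es, expected):
        assert lvef_from_measures(ed, es) == expected

    def test_nonpositive_ed_rejected(self):
        with pytest.raises(ValueError, match="end-diastolic"):
            lvef_from_measures(0.0, 10.0)

    def test_es_above_ed_warns_and_returns_negative(self):
        with pytest.warns(NegativeEjectionWarning):
            value = lvef_from_measures(100.0, 120.0)
        assert value == -20.0

    @given(
        st.floats(min_value=1.0, max_value=1e6),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, ed, frac, k):
        es = ed * frac
        assert lvef_from_measures(k * ed, k * es) == pytest.approx(
            lvef_from_measures(ed, es), abs=0.1
        )


def disk_image(centers, radius=6.0, shape=(64, 64), value=100.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    data = np.zeros(shape)
    for r0, c0 in centers:
        data[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = value
    return PlanarImage(data, (1.0, 1.0), SHORT_AXIS)


class TestSegment2D:
    def test_two_disks_pick_opposite_septal_side(self):
        img = disk_image([(32, 20), (32, 46)])
        mask = segment_lv_2d(img, 0.5, septal_side="+col")
        cols = np.nonzero(mask.data)[1]
        assert cols.max() < 32  # kept the low-col disk, opposite the +col RV
        mask2 = segment_lv_2d(img, 0.5, septal_side="-col")
        assert np.nonzero(mask2.data)[1].min() > 32  # flipped hint flips the pick

    def test_single_disk_returned_whole(self):
        img = disk_image([(32, 32)])
        mask = segment_lv_2d(img, 0.5)
        assert np.array_equal(mask.data, img.data > 0)

    def test_tied_components_rejected(self):
        # two disks at the same col coordinate tie along the +col septal axis
        img = disk_image([(20, 32), (44, 32)])
        with pytest.raises(ValueError, match="tie"):
            segment_lv_2d(img, 0.5, septal_side="+col")

    def test_merged_blobs_split_by_watershed(self):
        rr, cc = np.mgrid[:64, :64]
        data = 100.0 * np.exp(-((rr - 32) ** 2 + (cc - 24) ** 2) / 50.0)
        data += 90.0 * np.exp(-((rr - 32) ** 2 + (cc - 42) ** 2) / 50.0)
        img = PlanarImage(data, (1.0, 1.0), SHORT_AXIS)
        # low threshold keeps the bridge between the peaks: one component
        from skimage import measure as skmeasure

        binary = data > 0.2 * data.max()
        assert skmeasure.label(binary, connectivity=2).max() == 1
        mask = segment_lv_2d(img, 0.2, septal_side="+col")
        cols = np.nonzero(mask.data)[1]
        assert cols.mean() < 33  # kept the low-col half

    def test_no_signal_rejected(self):
        img = PlanarImage(np.zeros((16, 16)), (1.0, 1.0), SHORT_AXIS)
        with pytest.raises(ValueError, match="no positive pixel"):
            segment_lv_2d(img, 0.5)

    def test_mask_size_monotone_in_threshold(self):
        img = disk_image([(32, 20), (32, 46)])
        img.data[20:44, 10:30] += np.linspace(0, 40, 20)[None, :]
        sizes = [segment_lv_2d(img, t).size for t in (0.3, 0.4, 0.5, 0.6, 0.7)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_half_max_roi_area_matches_closed_form(self, small_pair, dose):
        # the half-max region of an ellipsoid sum-projection covers 3/4 of
        # the cavity footprint (chord > max/2 <=> in-plane radius^2 < 3/4)
        conc = first_pass_blood_concentration(dose).concentration_kBq_per_mL
        act = activity_map(small_pair.ed, {LABEL_LV: conc, LABEL_RV: conc})
        acq = AcquisitionConfig(poisson_noise=False, psf_fwhm_mm=2.2)
        img = project_sum(simulate_frame(act, acq), SHORT_AXIS)
        mask = segment_lv_2d(img, 0.5, septal_side="+col")
        footprint = ((small_pair.ed.data == LABEL_LV).sum(axis=0) > 0).sum()
        assert mask.size / footprint == pytest.approx(0.75, abs=0.05)


class TestCountLvef:
    def test_uniform_counts_reproduce_volume_ratio(self):
        ed = disk_image([(32, 20)], radius=10.0, value=11.0)
        es = disk_image([(32, 20)], radius=10.0, value=6.2)
        mask = RoiMask(ed.data > 0)
        res = count_lvef(ed, es, mask, mask)
        # masked totals proportional to (110, 62) -> the formula's 43.6%
        assert res.lvef_pct == 43.6

    def test_identical_phases_give_zero(self):
        ed = disk_image([(32, 20)])
        mask = RoiMask(ed.data > 0)
        assert count_lvef(ed, ed, mask, mask).lvef_pct == 0.0

    def test_background_subtraction_must_leave_positive_counts(self):
        ed = disk_image([(32, 20)], value=1.0)
        mask = RoiMask(ed.data > 0)
        with pytest.raises(ValueError, match="background"):
            count_lvef(ed, ed, mask, mask, background_per_pixel=10.0)

    def test_mask_shape_mismatch_rejected(self):
        ed = disk_image([(32, 20)])
        bad = RoiMask(np.ones((8, 8), dtype=bool))
        with pytest.raises(ValueError, match="mask shape"):
            count_lvef(ed, ed, bad, bad)


class TestSegment3D:
    def test_noiseless_phantom_recovers_cavity_volume(self, small_pair, dose, noiseless_acq):
        conc = first_pass_blood_concentration(dose).concentration_kBq_per_mL
        act = activity_map(small_pair.ed, {LABEL_LV: conc})
        vol = simulate_frame(act, noiseless_acq)
        mask = segment_lv_3d(vol, 0.5)
        measured = mask.size * vol.voxel_volume_mm3 / 1000.0
        assert measured == pytest.approx(small_pair.edv_cm3, rel=0.05)

    def test_mask_size_monotone_in_threshold(self, small_pair, dose):
        conc = first_pass_blood_concentration(dose).concentration_kBq_per_mL
        act = activity_map(small_pair.ed, {LABEL_LV: conc})
        vol = simulate_frame(act, AcquisitionConfig(poisson_noise=False, psf_fwhm_mm=4.0))
        sizes = [segment_lv_3d(vol, t).size for t in (0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_largest_component_kept(self):
        data = np.zeros((20, 20, 20))
        data[2:10, 2:10, 2:10] = 100.0  # 512 voxels
        data[14:18, 14:18, 14:18] = 100.0  # 64 voxels
        mask = segment_lv_3d(VoxelGrid(data, 1.0, KIND_COUNTS), 0.5)
        assert mask.size == 512

    def test_internal_holes_filled(self):
        data = np.zeros((16, 16, 16))
        data[2:12, 2:12, 2:12] = 100.0
        data[6, 6, 6] = 0.0
        mask = segment_lv_3d(VoxelGrid(data, 1.0, KIND_COUNTS), 0.5)
        assert mask.data[6, 6, 6]


class TestPipeline:
    CROP = (64, 64, 64)

    def test_noiseless_counts_match_reference_exactly(self, small_pair, dose, noiseless_acq):
        res = measure_lvef_pipeline(
            small_pair, dose, noiseless_acq,
            n_replicates=1, base_seed=0, crop_shape=self.CROP, perfect_masks=True,
        )
        assert res.lvef_pct == small_pair.reference_lvef_pct
        assert res.segmentation == "supplied"

    def test_counts_invariant_to_sensitivity_and_duration_noiseless(self, small_pair, dose):
        results = []
        for sens, dur in ((10.0, 3.0), (80.0, 1.5)):
            acq = AcquisitionConfig(
                poisson_noise=False, psf_fwhm_mm=0.0,
                sensitivity_counts_per_kBq_s=sens, frame_duration_s=dur,
            )
            res = measure_lvef_pipeline(
                small_pair, dose, acq, n_replicates=1, base_seed=0, crop_shape=self.CROP
            )
            results.append(res.lvef_pct)
        assert results[0] == results[1]

    def test_noisy_replicates_report_finite_spread(self, small_pair, dose):
        res = measure_lvef_pipeline(
            small_pair, dose, AcquisitionConfig(), n_replicates=4, base_seed=11,
            crop_shape=self.CROP,
        )
        stats = res.replicate_stats
        assert len(stats.values) == 4
        assert np.isfinite(stats.sd) and stats.sd >= 0.0
        assert stats.mean == pytest.approx(small_pair.reference_lvef_pct, abs=3.0)

    def test_volumetric_route_recovers_reference(self, small_pair, dose):
        res = measure_lvef_pipeline(
            small_pair, dose, AcquisitionConfig(), method="volumetric_3d",
            n_replicates=2, base_seed=5, crop_shape=self.CROP,
        )
        assert res.replicate_stats.mean == pytest.approx(
            small_pair.reference_lvef_pct, abs=3.0
        )
        assert res.axis is None

    def test_reproducible_given_base_seed(self, small_pair, dose):
        kwargs = dict(n_replicates=2, base_seed=21, crop_shape=self.CROP)
        a = measure_lvef_pipeline(small_pair, dose, AcquisitionConfig(), **kwargs)
        b = measure_lvef_pipeline(small_pair, dose, AcquisitionConfig(), **kwargs)
        assert a.replicate_stats.values == b.replicate_stats.values

    def test_unknown_method_rejected(self, small_pair, dose):
        with pytest.raises(ValueError, match="method"):
            measure_lvef_pipeline(small_pair, dose, AcquisitionConfig(), method="planimetry")


class TestThresholdSweep:
    def test_sweep_reports_stable_lvef_on_phantom(self, small_pair, dose):
        conc = first_pass_blood_concentration(dose).concentration_kBq_per_mL
        cmap = {LABEL_LV: conc, LABEL_RV: conc, LABEL_MYOCARDIUM: 0.0}
        acq = AcquisitionConfig(poisson_noise=False, psf_fwhm_mm=2.2)
        imgs = []
        for labels in (small_pair.ed, small_pair.es):
            frame = crop_center(simulate_frame(activity_map(labels, cmap), acq), (64, 64, 64))
            imgs.append(project_sum(frame, SHORT_AXIS))
        rows = threshold_sweep(imgs[0], imgs[1], thresholds=(0.4, 0.5, 0.6))
        assert [t for t, _ in rows] == [0.4, 0.5, 0.6]
        for _, lvef in rows:
            assert lvef == pytest.approx(small_pair.reference_lvef_pct, abs=3.0)
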