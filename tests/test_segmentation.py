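"""Segmentation: nuclei detection, splitting, cytoplasm growth, regions,
border removal, background estimation."""

import numpy as np
import pytest
from skimage.morphology import disk

from phenogate.segmentation import (
    RegionSet,
    SegmentationError,
    SegmentationParams,
    derive_regions,
    estimate_background,
    remove_border_cells,
    segment_cytoplasm,
    segment_field,
    segment_nuclei,
    split_touching_nuclei,
)
from phenogate.synthdata import FieldParams, render_field


def _disc_raster(shape, centers, radius, value=200.0, background=10.0):
    img = np.full(shape, background)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = value
    return img


FIXED = SegmentationParams(
    nuclear_threshold_method="fixed", fixed_threshold=100.0, min_nucleus_area_px=10,
    smoothing_sigma_px=0.0, fragment_merge_radius_px=0,
)


class TestSegmentNuclei:
    def test_blank_image_yields_zero_nuclei(self):
        mask = segment_nuclei(np.zeros((64, 64)), SegmentationParams())
        assert mask.max() == 0

    def test_five_disjoint_discs_found(self):
        img = _disc_raster((120, 120), [(20, 20), (20, 90), (60, 55), (100, 20), (100, 90)], 8)
        mask = segment_nuclei(img, FIXED)
        assert mask.max() == 5

    def test_area_filter_removes_small_disc(self):
        img = _disc_raster((60, 60), [(30, 30)], 2)  # area ~13 px
        params = SegmentationParams(
            nuclear_threshold_method="fixed", fixed_threshold=100.0,
            min_nucleus_area_px=50, smoothing_sigma_px=0.0,
        )
        assert segment_nuclei(img, params).max() == 0

    def test_min_area_monotonicity(self):
        img, _ = render_field({"healthy": 1.0}, 20, FieldParams(shape=(256, 256)), seed=4)
        counts = []
        for min_area in (10, 50, 120, 300):
            params = SegmentationParams(min_nucleus_area_px=min_area)
            counts.append(segment_nuclei(img.channels["hoechst"], params).max())
        assert counts == sorted(counts, reverse=True)

    def test_deterministic(self):
        img, _ = render_field({"healthy": 1.0}, 15, FieldParams(shape=(256, 256)), seed=9)
        a = segment_nuclei(img.channels["hoechst"], SegmentationParams())
        b = segment_nuclei(img.channels["hoechst"], SegmentationParams())
        np.testing.assert_array_equal(a, b)


class TestSplitTouchingNuclei:
    def _stuck_pair(self, radius=10, sep=1.5):
        img = _disc_raster((80, 80), [(40, 30), (40, 30 + int(sep * radius))], radius)
        nuclei = segment_nuclei(img, FIXED)
        assert nuclei.max() == 1  # overlapping discs form one component
        return nuclei, img

    def test_stuck_pair_is_split(self):
        nuclei, img = self._stuck_pair()
        out = split_touching_nuclei(nuclei, img, sensitivity=0.7)
        assert out.max() == 2

    def test_disabled_passes_through(self):
        nuclei, img = self._stuck_pair()
        out = split_touching_nuclei(nuclei, img, sensitivity=0.7, enabled=False)
        assert out.max() == 1

    def test_union_of_pixels_preserved(self):
        nuclei, img = self._stuck_pair()
        out = split_touching_nuclei(nuclei, img, sensitivity=0.7)
        np.testing.assert_array_equal(out > 0, nuclei > 0)

    @pytest.mark.parametrize("sensitivity", [0.1, 0.5, 0.9, 1.0])
    def test_single_convex_disc_never_split(self, sensitivity):
        img = _disc_raster((60, 60), [(30, 30)], 12)
        nuclei = segment_nuclei(img, FIXED)
        out = split_touching_nuclei(nuclei, img, sensitivity=sensitivity)
        assert out.max() == 1

    def test_sensitivity_monotone(self):
        nuclei, img = self._stuck_pair(sep=1.8)
        counts = [
            split_touching_nuclei(nuclei, img, sensitivity=s).max()
            for s in (0.2, 0.5, 0.8, 0.95)
        ]
        assert counts == sorted(counts)


class TestSegmentCytoplasm:
    def test_halo_grows_cell_strictly_containing_nucleus(self):
        img = _disc_raster((80, 80), [(40, 40)], 10, value=300.0, background=10.0)
        rr, cc = np.mgrid[:80, :80]
        img[((rr - 40) ** 2 + (cc - 40) ** 2 <= 18**2) & (img < 300)] = 80.0  # dim halo
        nuclei = segment_nuclei(img, FIXED)
        cell = segment_cytoplasm(img, nuclei, FIXED)
        assert np.all(cell[nuclei > 0] == nuclei[nuclei > 0])
        assert (cell > 0).sum() > (nuclei > 0).sum()

    def test_competing_halos_split_by_proximity(self):
        # two nuclei in one connected halo: each halo pixel strictly closer
        # to one nucleus must carry that nucleus's id (nearest-seed oracle)
        img = np.full((20, 20), 5.0)
        img[8:12, 3:7] = 300.0
        img[8:12, 13:17] = 300.0
        img[6:14, 1:19] = np.maximum(img[6:14, 1:19], 80.0)
        nuclei = segment_nuclei(img, FIXED)
        assert nuclei.max() == 2
        cell = segment_cytoplasm(img, nuclei, FIXED)
        from scipy import ndimage as ndi

        d1 = ndi.distance_transform_edt(nuclei != 1)
        d2 = ndi.distance_transform_edt(nuclei != 2)
        halo = cell > 0
        closer1 = halo & (d1 + 0.5 < d2)
        closer2 = halo & (d2 + 0.5 < d1)
        assert np.all(cell[closer1] == 1)
        assert np.all(cell[closer2] == 2)

    def test_background_pixels_excluded(self):
        img = _disc_raster((60, 60), [(30, 30)], 8, value=300.0, background=5.0)
        nuclei = segment_nuclei(img, FIXED)
        cell = segment_cytoplasm(img, nuclei, FIXED)
        assert np.all(cell[img < 50.0] == 0)


class TestDeriveRegions:
    def test_zero_erosion_identity(self):
        img = _disc_raster((60, 60), [(30, 30)], 10)
        nuclei = segment_nuclei(img, FIXED)
        regions = derive_regions(nuclei, nuclei.copy(), erosion_fraction=0.0)
        np.testing.assert_array_equal(regions.nuclei_eroded, regions.nuclei)

    def test_five_percent_erosion_area_ratio(self):
        # disc nucleus radius 20: eroded/original ~ (19/20)^2 ~ 0.90
        mask = np.zeros((60, 60), dtype=np.int32)
        mask[9:50, 9:50][disk(20) > 0] = 1
        regions = derive_regions(mask, mask.copy(), erosion_fraction=0.05)
        ratio = (regions.nuclei_eroded > 0).sum() / (regions.nuclei > 0).sum()
        assert 0.85 <= ratio <= 0.95

    def test_one_pixel_nucleus_erodes_to_empty(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[10, 10] = 1
        regions = derive_regions(mask, mask.copy(), erosion_fraction=0.05)
        assert (regions.nuclei_eroded > 0).sum() == 0
        assert 1 in regions.cell_ids  # cell retained

    def test_orphan_nucleus_is_error(self):
        nuclei = np.zeros((20, 20), dtype=np.int32)
        nuclei[5:8, 5:8] = 1
        cell = np.zeros_like(nuclei)
        with pytest.raises(SegmentationError, match="missing"):
            derive_regions(nuclei, cell, 0.05)

    def test_cytoplasm_is_cell_minus_nucleus(self):
        img = _disc_raster((60, 60), [(30, 30)], 10, value=300.0)
        rr, cc = np.mgrid[:60, :60]
        img[((rr - 30) ** 2 + (cc - 30) ** 2 <= 16**2) & (img < 300)] = 80.0
        nuclei = segment_nuclei(img, FIXED)
        cell = segment_cytoplasm(img, nuclei, FIXED)
        regions = derive_regions(nuclei, cell, 0.05)
        regions.validate()
        assert np.all((regions.cytoplasm > 0) == ((cell > 0) & (nuclei == 0)))


class TestRemoveBorderCells:
    def _two_cell_regions(self):
        nuclei = np.zeros((30, 30), dtype=np.int32)
        nuclei[0:5, 10:15] = 1  # touches top border
        nuclei[15:20, 10:15] = 2  # interior
        cell = nuclei.copy()
        cell[20:23, 10:15] = 2
        return derive_regions(nuclei, cell, 0.0)

    def test_border_nucleus_removed(self):
        out = remove_border_cells(self._two_cell_regions())
        assert out.cell_ids == [2]
        assert not (out.nuclei == 1).any()

    def test_interior_untouched(self):
        regions = self._two_cell_regions()
        out = remove_border_cells(regions)
        np.testing.assert_array_equal(out.nuclei == 2, regions.nuclei == 2)

    def test_cytoplasm_touching_border_retained(self):
        nuclei = np.zeros((30, 30), dtype=np.int32)
        nuclei[10:15, 10:15] = 1
        cell = nuclei.copy()
        cell[0:15, 10:15] = 1  # cytoplasm reaches the border, nucleus does not
        out = remove_border_cells(derive_regions(nuclei, cell, 0.0))
        assert out.cell_ids == [1]

    def test_all_interior_identity(self):
        img = _disc_raster((60, 60), [(30, 30)], 8)
        nuclei = segment_nuclei(img, FIXED)
        regions = derive_regions(nuclei, nuclei.copy(), 0.0)
        out = remove_border_cells(regions)
        np.testing.assert_array_equal(out.nuclei, regions.nuclei)


class TestEstimateBackground:
    def test_constant_raster_empty_mask(self):
        assert estimate_background(np.full((50, 50), 7.0), np.zeros((50, 50), np.int32)) == 7.0

    def test_cells_masked_out(self):
        raster = np.full((40, 40), 10.0)
        cell = np.zeros((40, 40), np.int32)
        cell[:, :20] = 1
        raster[:, :20] = 100.0
        assert estimate_background(raster, cell) == 10.0

    def test_too_few_background_pixels_is_error(self):
        cell = np.ones((40, 40), np.int32)
        with pytest.raises(SegmentationError, match="background"):
            estimate_background(np.ones((40, 40)), cell)

    def test_synthetic_offset_recovered_within_2pct(self):
        img, _ = render_field({"healthy": 1.0}, 30, FieldParams(shape=(256, 256)), seed=8)
        regions, backgrounds = segment_field(img, SegmentationParams())
        for channel, offset in (("hoechst", 100.0), ("annexin", 100.0), ("yopro", 100.0)):
            assert abs(backgrounds[channel] - offset) <= 0.02 * offset


class TestFieldLevel:
    def test_full_field_masks_deterministic(self, seg_params):
        img, _ = render_field({"healthy": 0.5, "necrotic": 0.5}, 30,
                              FieldParams(shape=(256, 256)), seed=12)
        r1, _ = segment_field(img, seg_params)
        r2, _ = segment_field(img, seg_params)
        for name in ("nuclei", "cell", "cytoplasm", "nuclei_eroded"):
            np.testing.assert_array_equal(getattr(r1, name), getattr(r2, name))

    def test_regionset_invariants_on_random_fields(self, seg_params):
        mix = {"healthy": 0.4, "initial_apoptotic": 0.2, "late_apoptotic": 0.2, "necrotic": 0.2}
        for seed in range(5):
            img, _ = render_field(mix, 20, FieldParams(shape=(256, 256)), seed=seed)
            regions, _ = segment_field(img, seg_params)
            regions.validate()

    def test_border_cells_are_removed_in_pipeline(self, seg_params):
        # no edge margin: some nuclei will straddle the frame border
        img, truth = render_field({"healthy": 1.0}, 60,
                                  FieldParams(shape=(300, 300), edge_margin_px=0.0), seed=21)
        n_border = sum(t.touches_border for t in truth)
        assert n_border > 0
        regions, _ = segment_field(img, seg_params)
        regions.validate()  # includes: no retained nucleus touches the border
        assert len(regions.cell_ids) < len(truth)
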