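"""Imaging pipeline: each stage against constructed fixtures and the
generator's ground truth, plus brute-force oracles for dilation/linking."""

import numpy as np
import pytest

from speckscreen import imaging, synthgen
from speckscreen.imaging import (
    FieldImagePair,
    ImagingError,
    SegmentationParams,
    analyze_field,
    analyze_well,
    dilate_nuclei,
    link_targets,
    percent_cells_with_specks,
    pool_field_results,
    reject_bright_cells,
    segment_nuclei,
    segment_specks,
)

from conftest import brute_force_dilate


def disk_image(shape, disks, value, background=100.0):
    """Paint disks (cy, cx, r) at a constant value over a flat background."""
    img = np.full(shape, background)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx, r in disks:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = value
    return img


class TestSegmentNuclei:
    def test_blank_image_gives_zero_nuclei(self):
        labels, n = segment_nuclei(np.zeros((64, 64)))
        assert n == 0 and labels.max() == 0

    def test_counts_well_separated_nuclei(self, small_field_spec):
        spec = small_field_spec(n_cells=50, noise_sd=5.0, seed=21)
        pair, truth = synthgen.generate_field(spec)
        _, n = segment_nuclei(pair.nuclear_channel)
        assert n == truth.n_cells_total == 50

    def test_watershed_splits_overlapping_disks(self):
        # two disks overlapping by less than one radius: connected
        # components see one object, the watershed must see two
        img = disk_image((64, 64), [(32, 24, 10), (32, 39, 10)], 1000.0)
        labels, n = segment_nuclei(img)
        assert n == 2
        from scipy import ndimage as ndi
        assert ndi.label(labels > 0)[0].max() == 1  # genuinely touching

    def test_fixed_threshold_method(self):
        img = disk_image((64, 64), [(20, 20, 8)], 1000.0)
        params = SegmentationParams(nuclei_threshold_method="fixed",
                                    nuclei_fixed_threshold=500.0)
        _, n = segment_nuclei(img, params)
        assert n == 1

    def test_objects_below_area_floor_removed(self):
        img = disk_image((64, 64), [(20, 20, 1)], 1000.0)  # ~5 px disk
        _, n = segment_nuclei(img, SegmentationParams(nuclei_min_area_px=20,
                                                      nuclei_smooth_sigma_px=0))
        assert n == 0


class TestRejectBrightCells:
    def _field(self, seed=31):
        spec = synthgen.FieldSpec(width_px=512, height_px=512, n_cells=60,
                                  speck_fraction=0.4, bright_cell_fraction=0.1,
                                  noise_sd=5.0, seed=seed)
        return synthgen.generate_field(spec)

    def test_infinite_threshold_rejects_none(self):
        pair, _ = self._field()
        labels, n = segment_nuclei(pair.nuclear_channel)
        params = SegmentationParams(bright_intensity_threshold=np.inf)
        selected, rejected = reject_bright_cells(labels, pair.reporter_channel,
                                                 np.zeros_like(labels, bool), params)
        assert rejected == 0
        assert np.array_equal(selected, labels)

    def test_threshold_below_all_rejects_all(self):
        pair, _ = self._field()
        labels, n = segment_nuclei(pair.nuclear_channel)
        params = SegmentationParams(bright_intensity_threshold=-1.0)
        selected, rejected = reject_bright_cells(labels, pair.reporter_channel,
                                                 np.zeros_like(labels, bool), params)
        assert rejected == n and selected.max() == 0

    def test_recovers_ground_truth_bright_count(self):
        pair, truth = self._field()
        labels, _ = segment_nuclei(pair.nuclear_channel)
        specks = segment_specks(pair.reporter_channel, pixel_size_um=pair.pixel_size_um)
        _, rejected = reject_bright_cells(labels, pair.reporter_channel, specks > 0)
        assert rejected == truth.n_bright

    def test_rejection_monotone_in_threshold(self):
        pair, _ = self._field()
        labels, _ = segment_nuclei(pair.nuclear_channel)
        empty = np.zeros_like(labels, bool)
        rejected = [
            reject_bright_cells(labels, pair.reporter_channel, empty,
                                SegmentationParams(bright_intensity_threshold=t))[1]
            for t in (5000.0, 1500.0, 200.0, -1.0)
        ]
        assert rejected == sorted(rejected)


class TestDilateNuclei:
    def test_subpixel_radius_is_identity(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:14, 10:14] = 1
        out = dilate_nuclei(labels, dilation_radius_um=0.2, pixel_size_um=0.65)
        assert np.array_equal(out, labels)

    def test_single_nucleus_matches_brute_force(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[18:23, 18:23] = 1
        out = dilate_nuclei(labels, 5.0, 1.0)
        assert np.array_equal(out, brute_force_dilate(labels, 5))

    def test_adjacent_nuclei_tile_by_nearest_with_lower_label_ties(self):
        labels = np.zeros((30, 48), dtype=np.int32)
        labels[13:17, 8:12] = 1
        labels[13:17, 30:34] = 2
        out = dilate_nuclei(labels, 12.0, 1.0)
        assert np.array_equal(out, brute_force_dilate(labels, 12))
        assert set(np.unique(out)) == {0, 1, 2}

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            labels = np.zeros((48, 48), dtype=np.int32)
            for lab in range(1, rng.integers(2, 6)):
                cy, cx = rng.integers(6, 42, 2)
                r = int(rng.integers(2, 4))
                yy, xx = np.mgrid[:48, :48]
                sel = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r) & (labels == 0)
                labels[sel] = lab
            r_px = int(rng.integers(2, 7))
            out = dilate_nuclei(labels, float(r_px), 1.0)
            assert np.array_equal(out, brute_force_dilate(labels, r_px))


class TestSegmentSpecks:
    def test_blank_reporter_gives_no_specks(self):
        labels = segment_specks(np.full((64, 64), 100.0))
        assert labels.max() == 0

    def test_recovers_rendered_speck_count(self):
        spec = synthgen.FieldSpec(width_px=512, height_px=512, n_cells=100,
                                  speck_fraction=0.4, bright_cell_fraction=0.0,
                                  noise_sd=5.0, seed=41)
        pair, truth = synthgen.generate_field(spec)
        labels = segment_specks(pair.reporter_channel, pixel_size_um=0.65)
        assert labels.max() == truth.n_speck_positive == 40

    def test_count_non_increasing_in_threshold(self):
        spec = synthgen.FieldSpec(width_px=512, height_px=512, n_cells=100,
                                  speck_fraction=0.4, seed=42)
        pair, _ = synthgen.generate_field(spec)
        counts = [
            int(segment_specks(pair.reporter_channel,
                               SegmentationParams(speck_threshold=t),
                               pixel_size_um=0.65).max())
            for t in (200.0, 500.0, 1500.0, 2500.0, 5000.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestLinkTargets:
    def test_no_specks_empty_set(self):
        cells = np.ones((16, 16), dtype=np.int32)
        positive, unassigned = link_targets(cells, np.zeros((16, 16), np.int32))
        assert positive == set() and unassigned == 0

    def test_cell_with_three_specks_counted_once(self):
        cells = np.ones((32, 32), dtype=np.int32)
        specks = np.zeros((32, 32), dtype=np.int32)
        specks[4:6, 4:6], specks[15:17, 15:17], specks[25:27, 25:27] = 1, 2, 3
        positive, _ = link_targets(cells, specks)
        assert positive == {1}

    def test_speck_outside_any_cell_is_unassigned(self):
        cells = np.zeros((32, 32), dtype=np.int32)
        cells[:16] = 1
        specks = np.zeros((32, 32), dtype=np.int32)
        specks[24:26, 10:12] = 1
        positive, unassigned = link_targets(cells, specks)
        assert positive == set() and unassigned == 1

    def test_random_instances_match_centroid_containment_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            cells = rng.integers(0, 5, (24, 24)).astype(np.int32)
            specks = np.zeros((24, 24), dtype=np.int32)
            for lab in range(1, rng.integers(2, 8)):
                cy, cx = rng.integers(2, 22, 2)
                specks[cy - 1 : cy + 2, cx - 1 : cx + 2] = lab
            positive, unassigned = link_targets(cells, specks)
            # oracle: exhaustive centroid computation per speck label
            exp_pos, exp_un = set(), 0
            for lab in np.unique(specks):
                if lab == 0:
                    continue
                ys, xs = np.nonzero(specks == lab)
                ri, ci = int(round(ys.mean())), int(round(xs.mean()))
                cid = int(cells[ri, ci])
                if cid > 0:
                    exp_pos.add(cid)
                else:
                    exp_un += 1
            assert positive == exp_pos and unassigned == exp_un


class TestPercentage:
    def test_basic_arithmetic(self):
        assert percent_cells_with_specks(40, 100) == 40.0
        assert percent_cells_with_specks(0, 7) == 0.0

    def test_zero_nuclei_is_an_error_naming_the_well(self):
        with pytest.raises(ImagingError, match="B07"):
            percent_cells_with_specks(3, 0, where="P1/B07")


class TestFieldAndWell:
    def test_full_pipeline_recovers_truth_within_tolerance(self, small_field_spec):
        spec = small_field_spec(seed=51)
        pair, truth = synthgen.generate_field(spec)
        res = analyze_field(pair)
        assert res.n_nuclei_selected == res.n_nuclei_total - res.n_nuclei_rejected_bright
        assert abs(res.pct_cells_with_specks - truth.pct_speck_positive) <= 5.0

    def test_pooling_arithmetic(self):
        f1 = imaging.FieldResult(50, 0, 50, 20, 40.0)
        f2 = imaging.FieldResult(50, 0, 50, 10, 20.0)
        well = pool_field_results([f1, f2], plate_id="P1", well="A01")
        assert well.n_nuclei_total == 100
        assert well.n_cells_with_specks == 30
        assert well.pct_cells_with_specks == pytest.approx(30.0)

    def test_duplicated_field_same_percentage(self, small_field_spec):
        pair, _ = synthgen.generate_field(small_field_spec(seed=52))
        one = analyze_well([pair], plate_id="P", well="A01")
        two = analyze_well([pair, pair], plate_id="P", well="A01")
        assert one.pct_cells_with_specks == pytest.approx(two.pct_cells_with_specks)

    def test_stimulated_exceeds_unstimulated(self):
        stim = synthgen.stimulated_field_spec(width_px=512, height_px=512,
                                              n_cells=100, seed=61)
        unstim = synthgen.unstimulated_field_spec(width_px=512, height_px=512,
                                                  n_cells=100, seed=61)
        p_stim, _ = synthgen.generate_field(stim)
        p_un, _ = synthgen.generate_field(unstim)
        assert (
            analyze_field(p_stim).pct_cells_with_specks
            > analyze_field(p_un).pct_cells_with_specks
        )

    def test_all_blank_fields_error(self):
        blank = FieldImagePair(np.zeros((64, 64)), np.zeros((64, 64)), 0.65)
        with pytest.raises(ImagingError, match="zero nuclei"):
            analyze_well([blank], plate_id="P", well="C03")

    def test_denominator_switch(self, small_field_spec):
        pair, _ = synthgen.generate_field(small_field_spec(seed=53))
        total = analyze_field(pair, SegmentationParams(denominator="total"))
        selected = analyze_field(pair, SegmentationParams(denominator="selected"))
        assert selected.pct_cells_with_specks >= total.pct_cells_with_specks

    def test_recovery_error_grows_with_noise(self, small_field_spec):
        errs = []
        for noise in (10.0, 300.0, 900.0):
            diffs = []
            for seed in range(4):
                pair, truth = synthgen.generate_field(
                    small_field_spec(seed=100 + seed, noise_sd=noise)
                )
                res = analyze_field(pair)
                diffs.append(abs(res.pct_cells_with_specks - truth.pct_speck_positive))
            errs.append(np.mean(diffs))
        assert errs[0] <= errs[1] <= errs[2]
        assert errs[0] <= 5.0
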