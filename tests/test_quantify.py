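"""Segmentation correctness against analytic and generator ground truth."""

import math
from datetime import date

import numpy as np
import pytest

from frondlab.design import ExperimentSpec, randomize_layout
from frondlab.errors import ImageFormatError, LayoutLookupError
from frondlab.imaging import ImagingRecord
from frondlab.labware import WellAddress
from frondlab.quantify import (
    SegmentationParams,
    fit_growth_rates,
    growth_curves,
    is_well_empty,
    measure_well,
    segment_fronds,
    total_frond_area,
)
from frondlab.synthetic import FrondSpec, synth_well_image

GREEN = (40, 200, 40)   # saturation ~204 of 255, well above the default threshold
GRAY = (110, 110, 110)  # zero saturation


def _blank_well(size=220):
    return np.full((size, size, 3), GRAY, dtype=np.uint8)


class TestSegmentFronds:
    def test_zero_saturation_image_has_no_contours(self):
        result = segment_fronds(_blank_well())
        assert not result.mask.any()
        assert result.kept == [] and result.rejected == []

    def test_non_rgb_input_rejected(self):
        with pytest.raises(ImageFormatError):
            segment_fronds(np.zeros((50, 50), dtype=np.uint8))

    def test_saturated_disk_area_within_2pct_of_analytic(self):
        image, _ = synth_well_image([FrondSpec(center=(110, 110), radius=30)], size=220)
        result = segment_fronds(image)
        assert len(result.kept) == 1
        assert result.kept[0].area == pytest.approx(math.pi * 30**2, rel=0.02)
        assert result.kept[0].roundness == pytest.approx(1.0, abs=0.1)

    def test_thin_line_rejected_disk_kept(self):
        image = _blank_well()
        yy, xx = np.ogrid[:220, :220]
        image[(xx - 110) ** 2 + (yy - 150) ** 2 <= 30**2] = GREEN
        image[60, 30:190] = GREEN  # 1-px saturated streak, roundness << 0.6
        result = segment_fronds(image)
        assert len(result.kept) == 1
        assert len(result.rejected) == 1
        assert result.rejected[0].roundness < 0.1
        assert result.rejected[0].area >= 50  # rejected for shape, not size

    def test_partition_is_exhaustive(self):
        image, _ = synth_well_image(
            [FrondSpec(center=(80, 80), radius=20), FrondSpec(center=(110, 60), radius=4)],
            size=160,
        )
        result = segment_fronds(image)
        from skimage import measure as skmeasure

        n_regions = int(skmeasure.label(result.mask, connectivity=2).max())
        assert len(result.kept) + len(result.rejected) == n_regions

    def test_raw_perimeter_area_variant(self):
        image, _ = synth_well_image([FrondSpec(center=(110, 110), radius=30)], size=220)
        params = SegmentationParams(use_perimeter_area_ratio=True, perimeter_area_max=0.5)
        result = segment_fronds(image, params)
        assert len(result.kept) == 1  # P/A for an r=30 disk is ~2/30 << 0.5

    def test_measured_area_matches_generator_pixel_count(self):
        # cross-module oracle: kept area == painted-pixel ground truth
        image, truth = synth_well_image(
            [FrondSpec(center=(70, 70), radius=18), FrondSpec(center=(110, 100), radius=12)],
            size=160,
        )
        result = segment_fronds(image)
        assert total_frond_area(result.kept) == pytest.approx(truth, rel=0.02)

    def test_enlarging_a_frond_never_decreases_area(self):
        areas = []
        for radius in (8, 12, 16, 20, 28):
            image, _ = synth_well_image([FrondSpec(center=(80, 80), radius=radius)], size=160)
            areas.append(total_frond_area(segment_fronds(image).kept))
        assert areas == sorted(areas)

    def test_raising_threshold_never_grows_mask(self):
        image, _ = synth_well_image(
            [FrondSpec(center=(80, 80), radius=20, saturation=150)],
            size=160, noise_sigma=8.0, seed=3,
        )
        sizes = [
            segment_fronds(image, SegmentationParams(saturation_threshold=t)).mask.sum()
            for t in (40, 80, 120, 160, 220)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestTotalFrondArea:
    def test_empty_list_is_zero(self):
        assert total_frond_area([]) == 0.0

    def test_two_disks_sum_to_analytic(self):
        image, _ = synth_well_image(
            [FrondSpec(center=(60, 60), radius=10), FrondSpec(center=(110, 110), radius=20)],
            size=180,
        )
        area = total_frond_area(segment_fronds(image).kept)
        assert area == pytest.approx(math.pi * (100 + 400), rel=0.02)

    def test_additivity_over_disjoint_sets(self):
        image, _ = synth_well_image(
            [FrondSpec(center=(60, 60), radius=10), FrondSpec(center=(110, 110), radius=20)],
            size=180,
        )
        kept = segment_fronds(image).kept
        assert total_frond_area(kept) == pytest.approx(sum(c.area for c in kept))


class TestIsWellEmpty:
    def test_empty_well(self):
        image, _ = synth_well_image([], size=160)
        assert is_well_empty(image)

    def test_occupied_well(self):
        image, _ = synth_well_image([FrondSpec(center=(80, 80), radius=15)], size=160)
        assert not is_well_empty(image)

    def test_subthreshold_speckle_counts_as_empty(self):
        # three 3-px-radius speckles, each ~28 px^2 < min_contour_area of 50
        specks = [FrondSpec(center=(60 + 20 * i, 70), radius=3) for i in range(3)]
        image, truth = synth_well_image(specks, size=160)
        assert truth > 0
        assert is_well_empty(image)


def _record(day: int, plate: int, well: str) -> ImagingRecord:
    return ImagingRecord(
        date=date(2026, 1, 1 + day), experiment="x", plate=plate, well=WellAddress.parse(well)
    )


def _measurement(day, plate, well, area):
    from frondlab.quantify import WellMeasurement

    return WellMeasurement(
        record=_record(day, plate, well), total_frond_area=area,
        n_contours_kept=1, n_contours_rejected=0,
    )


class TestGrowthCurves:
    @pytest.fixture
    def layout(self, toy_labware):
        spec = ExperimentSpec(
            name="x", genotypes=("g1",), media=("m1",), replicates=4,
            labware=toy_labware, seed=0,
        )
        return randomize_layout(spec)

    def test_replicate_mean_by_hand(self, layout):
        wells = [w for (_, _, w, _, _) in layout.assigned_wells()]
        areas = [100.0, 110.0, 90.0, 100.0]
        ms = [_measurement(0, 1, w, a) for w, a in zip(wells, areas)]
        curves = growth_curves(ms, layout)
        assert len(curves) == 1
        assert curves.loc[0, "mean_area"] == pytest.approx(100.0)
        assert curves.loc[0, "n"] == 4

    def test_constant_series_is_flat_with_zero_spread(self, layout):
        wells = [w for (_, _, w, _, _) in layout.assigned_wells()]
        ms = [_measurement(day, 1, w, 500.0) for day in range(3) for w in wells]
        curves = growth_curves(ms, layout)
        assert (curves["mean_area"] == 500.0).all()
        assert (curves["sd_area"] == 0.0).all()
        rates = fit_growth_rates(curves)
        assert rates.loc[0, "rate_per_day"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_days_absent_not_zero_filled(self, layout):
        wells = [w for (_, _, w, _, _) in layout.assigned_wells()]
        ms = [_measurement(0, 1, w, 100.0) for w in wells]
        ms += [_measurement(2, 1, w, 200.0) for w in wells[:2]]
        curves = growth_curves(ms, layout)
        assert sorted(curves["day"]) == [0, 2]
        assert curves.set_index("day").loc[2, "n"] == 2

    def test_unassigned_well_is_lookup_error(self, layout):
        with pytest.raises(LayoutLookupError):
            growth_curves([_measurement(0, 1, "D6", 10.0)], layout)

    def test_exact_exponential_recovered(self, layout):
        wells = [w for (_, _, w, _, _) in layout.assigned_wells()]
        ms = [
            _measurement(day, 1, w, 300.0 * math.exp(0.30 * day))
            for day in range(7)
            for w in wells
        ]
        rates = fit_growth_rates(growth_curves(ms, layout))
        assert rates.loc[0, "rate_per_day"] == pytest.approx(0.30, rel=1e-9)


class TestMeasureWell:
    def test_counts_and_total_are_consistent(self):
        image, truth = synth_well_image(
            [FrondSpec(center=(80, 80), radius=20), FrondSpec(center=(50, 100), radius=3)],
            size=160,
        )
        m = measure_well(image)
        assert m.n_contours_kept == 1
        assert m.n_contours_rejected == 1
        assert m.total_frond_area < truth  # speckle excluded from the total
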