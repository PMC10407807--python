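"""Grayscale normalization, resampling and ROI geometry."""

import numpy as np
import pytest

from carotexture import normalize as nz
from carotexture.errors import DegenerateReferenceError, EmptyMaskError, TraceError
from carotexture.texture import grayscale_median


def _image_with_regions(blood_vals, adv_vals):
    """Stack reference samples into a tiny image with disjoint masks."""
    blood = np.asarray(blood_vals).reshape(1, -1)
    adv = np.asarray(adv_vals).reshape(1, -1)
    w = max(blood.shape[1], adv.shape[1])
    img = np.zeros((2, w), dtype=int)
    img[0, :blood.shape[1]] = blood
    img[1, :adv.shape[1]] = adv
    bm = np.zeros_like(img, dtype=bool)
    bm[0, :blood.shape[1]] = True
    am = np.zeros_like(img, dtype=bool)
    am[1, :adv.shape[1]] = True
    return img, bm, am


class TestReferenceLevels:
    def test_blood_reference_is_darkest_pixel(self):
        img, bm, am = _image_with_regions([12, 7, 30], [100, 150, 200])
        blood, _ = nz.compute_reference_levels(img, bm, am)
        assert blood == 7

    def test_adventitia_reference_is_iqr_band_median(self):
        # 25th-75th band of {100..170} retains {120,130,140,150}; median 135
        img, bm, am = _image_with_regions([0], list(range(100, 180, 10)))
        _, adv = nz.compute_reference_levels(img, bm, am)
        assert adv == 135

    def test_already_standard_references_are_identity(self):
        img, bm, am = _image_with_regions([0, 0], [190, 190, 190])
        assert nz.compute_reference_levels(img, bm, am) == (0, 190)

    def test_degenerate_references_rejected(self):
        img, bm, am = _image_with_regions([200, 210], [50, 60, 70])
        with pytest.raises(DegenerateReferenceError):
            nz.compute_reference_levels(img, bm, am)

    def test_empty_mask_rejected(self):
        img, bm, am = _image_with_regions([10], [100])
        with pytest.raises(EmptyMaskError):
            nz.compute_reference_levels(img, np.zeros_like(bm), am)

    def test_full_median_switch(self):
        img, bm, am = _image_with_regions([0], list(range(100, 180, 10)))
        _, adv = nz.compute_reference_levels(img, bm, am, adventitia_method="full")
        assert adv == 135.0  # symmetric sample: plain median agrees here


class TestNormalizeGrayscale:
    @pytest.mark.parametrize(
        "blood,adv,value,expected",
        [
            (20, 120, 70, 95),     # (70-20)*190/100
            (20, 120, 20, 0),      # blood anchor
            (20, 120, 120, 190),   # adventitia anchor
            (0, 100, 200, 255),    # clipped from 380
        ],
    )
    def test_affine_map(self, blood, adv, value, expected):
        out = nz.normalize_grayscale(np.array([[value]]), blood, adv)
        assert out.pixels[0, 0] == expected

    def test_rounding_half_away_from_zero(self):
        # (49-0)*190/380 = 24.5 -> 25 away from zero (round-half-even would give 24)
        out = nz.normalize_grayscale(np.array([[49]]), 0, 380)
        assert out.pixels[0, 0] == 25

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            nz.normalize_grayscale(np.array([[1]]), 100, 100)

    def test_order_preserved(self, rng):
        img = rng.integers(0, 256, size=(20, 20))
        out = nz.normalize_grayscale(img, 10, 200).pixels
        flat_in, flat_out = img.ravel(), out.ravel().astype(int)
        order = np.argsort(flat_in, kind="stable")
        assert np.all(np.diff(flat_out[order]) >= 0)

    def test_idempotent_with_own_references(self, rng):
        """Renormalizing a standardized image with its own anchors (0, 190)
        is the identity map."""
        img = rng.integers(0, 256, size=(40, 40))
        once = nz.normalize_grayscale(img, 10, 200)
        twice = nz.normalize_grayscale(once.pixels, 0, 190)
        assert np.array_equal(twice.pixels, once.pixels)

    def test_recomputed_references_standard_without_clipping(self, rng):
        # intensity range chosen so the affine map never clips; then the
        # recomputed references land on the standard anchors
        img = rng.integers(70, 181, size=(40, 40))
        bm = np.zeros_like(img, dtype=bool)
        bm[:10] = True
        am = np.zeros_like(img, dtype=bool)
        am[-10:] = True
        img[-10:] = rng.integers(150, 181, size=(10, 40))  # bright adventitia
        img[0, 0] = 10  # darkest blood pixel
        blood, adv = nz.compute_reference_levels(img, bm, am)
        once = nz.normalize_grayscale(img, blood, adv)
        assert once.pixels.max() < 255  # no clipping occurred
        blood2, adv2 = nz.compute_reference_levels(once.pixels, bm, am)
        assert blood2 == 0
        assert abs(adv2 - 190) <= 1
        twice = nz.normalize_grayscale(once.pixels, blood2, adv2)
        assert np.max(np.abs(twice.pixels.astype(int) - once.pixels.astype(int))) <= 1

    def test_gsm_anchor_of_adventitia_band(self, rng):
        """After normalization the retained adventitia band has GSM 190 +/- 1."""
        img = rng.integers(0, 256, size=(50, 50))
        am = np.zeros_like(img, dtype=bool)
        am[-15:] = True
        bm = np.zeros_like(img, dtype=bool)
        bm[:5] = True
        blood, adv = nz.compute_reference_levels(img, bm, am)
        out = nz.normalize_grayscale(img, blood, adv)
        vals = img[am]
        q25, q75 = np.percentile(vals, [25, 75])
        band = am & (img >= q25) & (img <= q75)
        assert abs(grayscale_median(out.pixels, band) - 190) <= 1


class TestResample:
    def test_noop_at_target_density(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        out, d = nz.resample_to_density(img, 190.0)
        assert d == 190.0
        assert out is img

    def test_constant_preserved_on_upsampling(self):
        img = np.full((2, 2), 37, dtype=np.uint8)
        out, _ = nz.resample_to_density(img, 95.0, 190.0)
        assert out.shape == (4, 4)
        assert np.all(out == 37)

    def test_bilinear_decimation_of_row_ramp(self):
        # rows 0,2,4,6 at 380 px/mm -> centers at input rows 0.5 and 2.5 -> 1,5
        img = np.repeat(np.array([[0], [2], [4], [6]]), 4, axis=1).astype(np.uint8)
        out, _ = nz.resample_to_density(img, 380.0, 190.0)
        assert out.shape == (2, 2)
        assert np.all(out[0] == 1) and np.all(out[1] == 5)

    def test_unknown_density_rejected(self):
        with pytest.raises(ValueError):
            nz.resample_to_density(np.zeros((2, 2)), None)


class TestRoiMask:
    def _traces(self, y_upper, y_lower, x_max=250):
        return [[0, y_upper], [x_max, y_upper]], [[0, y_lower], [x_max, y_lower]]

    def test_horizontal_band_geometry(self):
        upper, lower = self._traces(10, 14)
        roi = nz.trace_to_roi_mask(upper, lower, (30, 260), pixel_density=190)
        assert roi.n_pixels == 190 * 4
        cols = np.where(roi.mask.any(axis=0))[0]
        rows = np.where(roi.mask.any(axis=1))[0]
        assert len(cols) == 190 and cols[-1] == 250  # distal end of the trace
        assert list(rows) == [10, 11, 12, 13]  # half-open at the lower boundary

    def test_band_thinner_than_one_pixel_rejected(self):
        upper, lower = self._traces(10, 10.5)
        with pytest.raises(TraceError):
            nz.trace_to_roi_mask(upper, lower, (30, 260), pixel_density=190)

    def test_short_trace_rejected(self):
        upper, lower = self._traces(10, 14, x_max=95)  # 0.5 mm at 190 px/mm
        with pytest.raises(TraceError):
            nz.trace_to_roi_mask(upper, lower, (30, 260), pixel_density=190)

    def test_crossing_boundaries_rejected(self):
        upper = [[0, 12], [250, 12]]
        lower = [[0, 14], [250, 10]]
        with pytest.raises(TraceError):
            nz.trace_to_roi_mask(upper, lower, (30, 260), pixel_density=190)

    def test_sloped_wall_arc_length_window(self):
        # a gently sloped wall: the window is measured in arc length, so
        # slightly fewer columns than 190 are selected
        upper = [[0, 10], [250, 20]]
        lower = [[0, 20], [250, 30]]
        roi = nz.trace_to_roi_mask(upper, lower, (40, 260), pixel_density=190)
        cols = np.where(roi.mask.any(axis=0))[0]
        assert 180 <= len(cols) <= 190
        assert cols[-1] == 250
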