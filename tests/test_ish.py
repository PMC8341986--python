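"""8-bit conversion, IsoData thresholding, area fractions and slice quantification."""

import numpy as np
import pytest
from skimage.filters import threshold_isodata

from laminamap import (
    ISHImage,
    LAYERS,
    ROISet,
    area_fraction,
    auto_threshold,
    quantify_slices,
    signal_intensity,
    to_8bit,
)
from laminamap.ish import isodata_threshold, propose_background


def _img(arr):
    return ISHImage(np.asarray(arr, dtype=float))


class TestTo8bit:
    def test_constant_image_maps_to_zero(self):
        out = to_8bit(_img(np.full((3, 3), 7.0)))
        assert out.pixels.dtype == np.uint8
        assert not out.pixels.any()

    def test_linear_map_with_round_half_up(self):
        out = to_8bit(_img([[0.0, 0.5], [1.0, 1.0]]))
        assert out.pixels[0, 0] == 0
        assert out.pixels[0, 1] == 128  # 127.5 rounds up
        assert out.pixels[1, 0] == 255

    def test_full_range_8bit_image_unchanged(self, rng):
        px = rng.integers(0, 256, (10, 10))
        px[0, 0], px[-1, -1] = 0, 255
        out = to_8bit(_img(px))
        np.testing.assert_array_equal(out.pixels, px)

    def test_monotone(self, rng):
        px = rng.normal(50, 20, (12, 12))
        out = to_8bit(_img(px)).pixels
        flat_in, flat_out = px.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order].astype(int)) >= 0)


class TestThreshold:
    def test_two_spike_histogram(self):
        px = np.concatenate([np.full(50, 10), np.full(50, 200)]).reshape(10, 10)
        level = isodata_threshold(px)
        assert 10 < level < 200
        mask = auto_threshold(ISHImage(px.astype(np.uint8)))
        assert mask.sum() == 50

    def test_constant_image_warns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = auto_threshold(ISHImage(np.full((4, 4), 9, dtype=np.uint8)))
        assert not mask.any()

    def test_manual_level_zero_selects_everything(self):
        mask = auto_threshold(ISHImage(np.zeros((4, 4), dtype=np.uint8)), manual=0)
        assert mask.all()

    def test_level_close_to_skimage(self, rng):
        for _ in range(10):
            px = np.concatenate(
                [rng.normal(40, 15, 300), rng.normal(190, 25, 200)]
            ).clip(0, 255).astype(np.uint8).reshape(25, 20)
            ours = isodata_threshold(px)
            assert abs(ours - threshold_isodata(px)) <= 1.0


class TestAreaFraction:
    def test_counts_pixels(self):
        roi = np.zeros((20, 20), dtype=bool)
        roi[:10, :10] = True
        mask = np.zeros((20, 20), dtype=bool)
        mask[:5, :5] = True  # 25 pixels inside the 100-pixel ROI
        assert area_fraction(mask, roi) == pytest.approx(25.0)

    def test_empty_and_full(self):
        roi = np.ones((5, 5), dtype=bool)
        assert area_fraction(np.zeros((5, 5), bool), roi) == 0.0
        assert area_fraction(np.ones((5, 5), bool), roi) == 100.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty ROI"):
            area_fraction(np.ones((4, 4), bool), np.zeros((4, 4), bool))

    def test_union_is_weighted_mean(self, rng):
        # AF over a disjoint union is the pixel-count weighted mean of the parts
        for _ in range(20):
            mask = rng.random((30, 30)) < 0.3
            a = np.zeros((30, 30), bool)
            b = np.zeros((30, 30), bool)
            a[:15] = rng.random((15, 30)) < 0.5
            b[15:] = rng.random((15, 30)) < 0.5
            if not (a.any() and b.any()):
                continue
            af_union = area_fraction(mask, a | b)
            expected = (
                area_fraction(mask, a) * a.sum() + area_fraction(mask, b) * b.sum()
            ) / (a.sum() + b.sum())
            assert af_union == pytest.approx(expected)


def _band_rois(shape=(50, 10)):
    masks = {}
    for i, name in enumerate(LAYERS):
        m = np.zeros(shape, bool)
        m[i * 10 : (i + 1) * 10] = True
        masks[name] = m
    bg = np.zeros(shape, bool)
    bg[40:] = True
    return ROISet(layer_masks=masks, background=bg)


class TestSignalIntensity:
    def _image_with_af(self, af_per_band):
        """Binary image with the requested per-band signal percentages."""
        px = np.zeros((50, 10))
        for i, af in enumerate(af_per_band):
            n = int(round(af))  # af% of each 100-pixel band
            band = px[i * 10 : (i + 1) * 10].reshape(-1)
            band[:n] = 255.0
        return ISHImage(px)

    def test_background_subtraction(self):
        img = self._image_with_af([40, 20, 10, 8, 5])  # last band is background
        out = signal_intensity(img, _band_rois(), manual_threshold=128)
        np.testing.assert_allclose(out, [35, 15, 5, 3])

    def test_background_above_layer_clips_to_zero(self):
        img = self._image_with_af([2, 5, 5, 5, 10])
        out = signal_intensity(img, _band_rois(), manual_threshold=128)
        assert out[0] == 0.0

    def test_zero_signal_image(self):
        with pytest.warns(UserWarning, match="constant"):
            out = signal_intensity(ISHImage(np.zeros((50, 10))), _band_rois())
        np.testing.assert_allclose(out, 0.0)

    def test_offset_invariance(self, rng):
        px = rng.integers(10, 200, (50, 10)).astype(float)
        a = signal_intensity(ISHImage(px), _band_rois())
        b = signal_intensity(ISHImage(px + 37.0), _band_rois())
        np.testing.assert_allclose(a, b)


class TestQuantifySlices:
    def test_single_slice_equals_signal_intensity(self):
        img = TestSignalIntensity()._image_with_af([30, 10, 5, 2, 1])
        rois = _band_rois()
        vec, n = quantify_slices([(img, rois)], manual_threshold=128)
        np.testing.assert_allclose(vec, signal_intensity(img, rois, 128))
        assert n == 1

    def test_mean_and_permutation_invariance(self):
        s1 = TestSignalIntensity()._image_with_af([30, 0, 0, 0, 0])
        s2 = TestSignalIntensity()._image_with_af([10, 0, 0, 0, 0])
        rois = _band_rois()
        v12, _ = quantify_slices([(s1, rois), (s2, rois)], manual_threshold=128)
        v21, _ = quantify_slices([(s2, rois), (s1, rois)], manual_threshold=128)
        assert v12[0] == pytest.approx(20.0)
        np.testing.assert_allclose(v12, v21)

    def test_zero_slices_rejected(self):
        with pytest.raises(ValueError, match="at least one slice"):
            quantify_slices([])


class TestROISet:
    def test_overlapping_masks_rejected(self):
        masks = {name: np.ones((4, 4), bool) for name in LAYERS}
        with pytest.raises(ValueError, match="overlaps"):
            ROISet(layer_masks=masks, background=np.ones((4, 4), bool))

    def test_empty_layer_rejected(self):
        rois = _band_rois()
        masks = dict(rois.layer_masks)
        masks["Op"] = np.zeros((50, 10), bool)
        with pytest.raises(ValueError, match="empty"):
            ROISet(layer_masks=masks, background=rois.background)


def test_propose_background_finds_darkest_patch():
    px = np.full((40, 40), 120.0)
    px[25:35, 5:15] = 3.0
    mask = propose_background(ISHImage(px), window=(10, 10))
    assert mask.sum() == 100
    assert mask[30, 10]
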