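"""Per-ROI metric computation, normalization, and their invariances."""

import math

import numpy as np
import pytest

from oralscreen import (
    FEATURE_FIELDS,
    Modality,
    RGBImage,
    ROI,
    ValidationError,
    channel_mfi,
    compute_features,
    grayscale,
    normalize_by_split,
    normalize_lesion,
)
from oralscreen.features import RATIO_EPS, UndefinedFeatureWarning, split_roi

from conftest import const_image, full_roi, random_image


def naive_features(image, roi):
    """Per-pixel loop oracle for compute_features (independent of numpy
    vectorization)."""
    vals = {"r": [], "g": [], "b": [], "gray": [], "rg": [], "rb": [], "bg": []}
    for r in range(image.height):
        for c in range(image.width):
            if not roi.mask[r, c]:
                continue
            R, G, B = image.pixels[r, c]
            vals["r"].append(R)
            vals["g"].append(G)
            vals["b"].append(B)
            vals["gray"].append(0.299 * R + 0.587 * G + 0.114 * B)
            if G > RATIO_EPS:
                vals["rg"].append(R / G)
                vals["bg"].append(B / G)
            if B > RATIO_EPS:
                vals["rb"].append(R / B)

    def mean(xs):
        return sum(xs) / len(xs) if xs else math.nan

    def sd(xs):
        m = mean(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))

    return {
        "mfi_r": mean(vals["r"]),
        "mfi_g": mean(vals["g"]),
        "mfi_b": mean(vals["b"]),
        "mean_rg": mean(vals["rg"]),
        "mean_rb": mean(vals["rb"]),
        "mean_bg": mean(vals["bg"]),
        "mfi_gray": mean(vals["gray"]),
        "sd_r": sd(vals["r"]),
        "sd_g": sd(vals["g"]),
        "sd_b": sd(vals["b"]),
        "sd_gray": sd(vals["gray"]),
        "mfi_ratio_rg": mean(vals["r"]) / mean(vals["g"]),
    }


class TestChannelMFI:
    def test_constant_image(self):
        img = const_image(4, 4, (0.1, 0.5, 0.9))
        assert channel_mfi(img, full_roi(4, 4), "G") == pytest.approx(0.5)

    def test_two_pixel_mean(self):
        img = const_image(1, 2, (0, 0, 0)).pixels.copy()
        img[0, 0, 1] = 100 / 255
        img[0, 1, 1] = 200 / 255
        image = RGBImage(img, Modality.FLUORESCENCE)
        assert channel_mfi(image, full_roi(1, 2), "G") == pytest.approx(150 / 255)

    def test_single_pixel_identity(self, rng):
        img = random_image(rng, 3, 3)
        roi = ROI.from_coords([(2, 1)], 3, 3)
        assert channel_mfi(img, roi, "R") == img.pixels[2, 1, 0]

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError, match="does not match"):
            channel_mfi(random_image(rng, 3, 3), full_roi(4, 4), "R")


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected", [((0, 1, 0), 0.587), ((1, 1, 1), 1.0), ((0, 0, 0), 0.0)]
    )
    def test_luma_weights(self, rgb, expected):
        img = const_image(1, 1, rgb)
        assert grayscale(img)[0, 0] == pytest.approx(expected)


class TestComputeFeatures:
    def test_constant_image_ratios_and_zero_sd(self):
        fv = compute_features(const_image(3, 3, (0.2, 0.4, 0.8)), full_roi(3, 3))
        assert fv.mean_rg == pytest.approx(0.5)
        assert fv.mean_bg == pytest.approx(2.0)
        assert fv.mean_rb == pytest.approx(0.25)
        assert fv.sd_r == fv.sd_g == fv.sd_b == fv.sd_gray == 0.0
        # on constant images the two red/green conventions agree
        assert fv.mfi_ratio_rg == pytest.approx(fv.mean_rg)
        # channel-ratio identity: R/B = (R/G) / (B/G)
        assert fv.mean_rb == pytest.approx(fv.mean_rg / fv.mean_bg)

    def test_ratio_conventions_differ_on_nonconstant_images(self):
        px = np.zeros((1, 2, 3))
        px[0, 0] = (0.2, 0.4, 0.5)
        px[0, 1] = (0.6, 0.6, 0.5)
        fv = compute_features(RGBImage(px, Modality.FLUORESCENCE), full_roi(1, 2))
        assert fv.mean_rg == pytest.approx((0.5 + 1.0) / 2)  # mean of per-pixel ratios
        assert fv.mfi_ratio_rg == pytest.approx(0.4 / 0.5)  # ratio of channel means

    def test_denominator_guard_flags_undefined_ratio(self):
        px = np.zeros((2, 2, 3))
        px[:, :, 0] = 0.5  # red present, green identically zero
        img = RGBImage(px, Modality.FLUORESCENCE)
        with pytest.warns(UndefinedFeatureWarning, match="mean_rg"):
            fv = compute_features(img, full_roi(2, 2), site_id="sX")
        assert math.isnan(fv.mean_rg)
        assert "mean_rg" in fv.undefined_fields

    def test_agrees_with_naive_loop_oracle(self, rng):
        for _ in range(5):
            img = random_image(rng, 8, 8)
            mask = rng.random((8, 8)) < 0.5
            mask[0, 0] = True
            roi = ROI(mask)
            fv = compute_features(img, roi).as_dict()
            oracle = naive_features(img, roi)
            for name in FEATURE_FIELDS:
                assert fv[name] == pytest.approx(oracle[name], abs=1e-12), name

    def test_permutation_invariant_in_pixel_order(self, rng):
        img = random_image(rng, 6, 6)
        coords = [(r, c) for r in range(6) for c in range(6) if rng.random() < 0.6]
        coords = coords or [(0, 0)]
        roi_fwd = ROI.from_coords(coords, 6, 6)
        roi_rev = ROI.from_coords(list(reversed(coords)), 6, 6)
        assert compute_features(img, roi_fwd) == compute_features(img, roi_rev)


class TestNormalizeLesion:
    def test_identical_vectors_normalize_to_one(self, rng):
        fv = compute_features(random_image(rng), full_roi(8, 8))
        norm = normalize_lesion(fv, fv)
        assert all(v == 1.0 for v in norm.as_dict().values())

    def test_division_examples(self):
        lesion = compute_features(const_image(2, 2, (0.50 * 0.4, 0.4, 0.2)), full_roi(2, 2))
        contra = compute_features(const_image(2, 2, (0.45 * 0.4, 0.4, 0.2)), full_roi(2, 2))
        norm = normalize_lesion(lesion, contra)
        assert norm.mfi_ratio_rg == pytest.approx(0.50 / 0.45)  # ~1.111

    def test_green_loss_normalizes_below_one(self):
        lesion = compute_features(const_image(2, 2, (0.1, 0.30, 0.2)), full_roi(2, 2))
        contra = compute_features(const_image(2, 2, (0.1, 0.50, 0.2)), full_roi(2, 2))
        assert normalize_lesion(lesion, contra).mfi_g == pytest.approx(0.6)

    def test_zero_reference_with_differing_lesion_is_undefined(self):
        lesion = compute_features(const_image(2, 2, (0.5, 0.5, 0.5)), full_roi(2, 2))
        contra = compute_features(const_image(2, 2, (0.0, 0.5, 0.5)), full_roi(2, 2))
        norm = normalize_lesion(lesion, contra)
        assert math.isnan(norm.mfi_r)
        assert "mfi_r" in norm.undefined_fields


class TestSplitNormalization:
    def test_two_pixel_roi_splits_along_rows(self):
        px = np.zeros((2, 1, 3))
        px[0, 0] = (0.1, 0.4, 0.2)
        px[1, 0] = (0.1, 0.2, 0.2)
        img = RGBImage(px, Modality.FLUORESCENCE)
        norm = normalize_by_split(img, full_roi(2, 1))
        assert norm.mfi_g == pytest.approx(2.0)

    def test_wide_roi_splits_along_columns(self):
        px = np.zeros((1, 4, 3))
        px[0, :, 1] = (0.8, 0.8, 0.2, 0.2)
        px[0, :, 0] = px[0, :, 2] = 0.5
        img = RGBImage(px, Modality.FLUORESCENCE)
        norm = normalize_by_split(img, full_roi(1, 4))
        assert norm.mfi_g == pytest.approx(4.0)  # first (left) half is the numerator

    def test_odd_count_gives_extra_pixel_to_numerator(self):
        roi = full_roi(5, 1)
        first, second = split_roi(roi)
        assert first.pixel_count == 3 and second.pixel_count == 2

    def test_homogeneous_image_normalizes_to_exactly_one(self):
        img = const_image(6, 4, (0.15, 0.61, 0.33))
        norm = normalize_by_split(img, full_roi(6, 4))
        assert all(v == 1.0 for v in norm.as_dict().values())

    def test_single_pixel_roi_rejected(self, rng):
        img = random_image(rng, 3, 3)
        with pytest.raises(ValidationError, match=">= 2"):
            normalize_by_split(img, ROI.from_coords([(1, 1)], 3, 3))


class TestScaleInvariance:
    def test_normalized_features_unchanged_by_global_scaling(self, rng):
        img = random_image(rng, 10, 10, low=0.2, high=0.9)
        roi_mask = np.zeros((10, 10), dtype=bool)
        roi_mask[2:8, 1:5] = True
        contra_mask = np.zeros((10, 10), dtype=bool)
        contra_mask[2:8, 6:10] = True
        lesion, contra = ROI(roi_mask), ROI(contra_mask)

        def normalized(image):
            return normalize_lesion(
                compute_features(image, lesion), compute_features(image, contra)
            ).as_dict()

        base = normalized(img)
        scaled = normalized(img.scaled(0.5))
        for name in FEATURE_FIELDS:
            assert scaled[name] == pytest.approx(base[name], rel=1e-12), name

    def test_split_normalization_unchanged_by_global_scaling(self, rng):
        img = random_image(rng, 9, 5, low=0.2, high=0.9)
        roi = full_roi(9, 5)
        base = normalize_by_split(img, roi).as_dict()
        scaled = normalize_by_split(img.scaled(0.5), roi).as_dict()
        for name in FEATURE_FIELDS:
            assert scaled[name] == pytest.approx(base[name], rel=1e-12), name
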