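"""Per-ROI image metrics and their normalized ratios.

Twelve metrics are computed over the pixels of an ROI:

* ``mfi_r``, ``mfi_g``, ``mfi_b`` — mean intensity of each channel (the
  mean fluorescence intensity, MFI, when applied to fluorescence images);
* ``mean_rg``, ``mean_rb``, ``mean_bg`` — means of the per-pixel channel
  ratios R/G, R/B and B/G (pixels whose denominator channel is at or below
  one 8-bit quantum are excluded, which keeps sensor-noise pixels from
  producing unbounded ratios);
* ``mfi_gray`` — mean of the BT.601 luma grayscale conversion;
* ``sd_r``, ``sd_g``, ``sd_b``, ``sd_gray`` — population standard
  deviations of the channels and the grayscale image;
* ``mfi_ratio_rg`` — the ratio of channel MFIs, mean(R)/mean(G).  This is
  the "red/green MFI ratio" used as the headline classification feature;
  note it differs from ``mean_rg`` (mean of per-pixel ratios) whenever the
  image is not constant.

Normalization divides each lesion-ROI metric by the same metric from a
reference region: the contralateral clinically-normal ROI of the same
subject for abnormal sites, or the second half of the site's own ROI for
clinically normal sites (split normalization).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from typing import Dict, Tuple

import numpy as np

from .datamodel import RGBImage, ROI, ValidationError

#: Canonical metric order used in tables and reports.
FEATURE_FIELDS: Tuple[str, ...] = (
    "mfi_r",
    "mfi_g",
    "mfi_b",
    "mean_rg",
    "mean_rb",
    "mean_bg",
    "mfi_gray",
    "sd_r",
    "sd_g",
    "sd_b",
    "sd_gray",
    "mfi_ratio_rg",
)

#: Denominator guard for per-pixel channel ratios: one 8-bit quantum.
RATIO_EPS = 1.0 / 255.0

#: BT.601 luma weights for grayscale conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


class UndefinedFeatureWarning(UserWarning):
    """A metric could not be computed (e.g. every ratio denominator was ~0)."""


@dataclass(frozen=True)
class FeatureVector:
    """The twelve per-ROI metrics. Undefined metrics are NaN."""

    mfi_r: float
    mfi_g: float
    mfi_b: float
    mean_rg: float
    mean_rb: float
    mean_bg: float
    mfi_gray: float
    sd_r: float
    sd_g: float
    sd_b: float
    sd_gray: float
    mfi_ratio_rg: float

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_FIELDS}

    @property
    def undefined_fields(self) -> Tuple[str, ...]:
        return tuple(n for n in FEATURE_FIELDS if math.isnan(getattr(self, n)))


@dataclass(frozen=True)
class NormalizedFeatureVector:
    """Field-wise lesion/reference ratios of two FeatureVectors."""

    mfi_r: float
    mfi_g: float
    mfi_b: float
    mean_rg: float
    mean_rb: float
    mean_bg: float
    mfi_gray: float
    sd_r: float
    sd_g: float
    sd_b: float
    sd_gray: float
    mfi_ratio_rg: float

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_FIELDS}

    @property
    def undefined_fields(self) -> Tuple[str, ...]:
        return tuple(n for n in FEATURE_FIELDS if math.isnan(getattr(self, n)))


def grayscale(image: RGBImage) -> np.ndarray:
    """Per-pixel BT.601 luma: 0.299 R + 0.587 G + 0.114 B."""
    wr, wg, wb = GRAY_WEIGHTS
    px = image.pixels
    return wr * px[:, :, 0] + wg * px[:, :, 1] + wb * px[:, :, 2]


_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


def channel_mfi(image: RGBImage, roi: ROI, channel: str) -> float:
    """Arithmetic mean of one channel over the ROI pixels."""
    roi.check_compatible(image)
    try:
        idx = _CHANNEL_INDEX[channel.upper()]
    except KeyError:
        raise ValidationError(f"unknown channel {channel!r}; expected R, G or B") from None
    return float(image.pixels[:, :, idx][roi.mask].mean())


def _ratio_mean(num: np.ndarray, den: np.ndarray, name: str, site: str) -> float:
    valid = den > RATIO_EPS
    if not valid.any():
        warnings.warn(
            f"{name} undefined for site {site!r}: every ROI pixel excluded by "
            f"the denominator guard (<= {RATIO_EPS:.6g})",
            UndefinedFeatureWarning,
            stacklevel=3,
        )
        return math.nan
    return float((num[valid] / den[valid]).mean())


def compute_features(image: RGBImage, roi: ROI, site_id: str = "") -> FeatureVector:
    """Compute all twelve metrics over the ROI pixels of ``image``."""
    roi.check_compatible(image)
    px = image.pixels[roi.mask]  # (N, 3)
    r, g, b = px[:, 0], px[:, 1], px[:, 2]
    wr, wg, wb = GRAY_WEIGHTS
    gray = wr * r + wg * g + wb * b
    mfi_r = float(r.mean())
    mfi_g = float(g.mean())
    mfi_b = float(b.mean())
    return FeatureVector(
        mfi_r=mfi_r,
        mfi_g=mfi_g,
        mfi_b=mfi_b,
        mean_rg=_ratio_mean(r, g, "mean_rg", site_id),
        mean_rb=_ratio_mean(r, b, "mean_rb", site_id),
        mean_bg=_ratio_mean(b, g, "mean_bg", site_id),
        mfi_gray=float(gray.mean()),
        sd_r=float(r.std()),  # population SD (ddof=0)
        sd_g=float(g.std()),
        sd_b=float(b.std()),
        sd_gray=float(gray.std()),
        mfi_ratio_rg=(mfi_r / mfi_g) if mfi_g > 0.0 else math.nan,
    )


def _safe_ratio(lesion: float, reference: float) -> float:
    """lesion / reference with identical metrics mapping to exactly 1.

    Identical values (including 0/0, e.g. both standard deviations of a
    constant image) normalize to 1; a zero reference with a differing lesion
    value is undefined (NaN).
    """
    if math.isnan(lesion) or math.isnan(reference):
        return math.nan
    if lesion == reference:
        return 1.0
    if reference == 0.0:
        return math.nan
    return lesion / reference


def normalize_lesion(
    lesion_fv: FeatureVector, reference_fv: FeatureVector
) -> NormalizedFeatureVector:
    """Field-wise ratio of lesion metrics to contralateral/reference metrics."""
    values = {
        name: _safe_ratio(getattr(lesion_fv, name), getattr(reference_fv, name))
        for name in FEATURE_FIELDS
    }
    return NormalizedFeatureVector(**values)


def split_roi(roi: ROI) -> Tuple[ROI, ROI]:
    """Split an ROI into two equal-count halves.

    Pixels are ordered along the longer bounding-box axis (ties favour the
    row axis) and the first half — which receives the extra pixel for odd
    counts — is the numerator half of split normalization.
    """
    if roi.pixel_count < 2:
        raise ValidationError("split normalization requires an ROI of >= 2 pixels")
    r0, r1, c0, c1 = roi.bounding_box()
    axis = 0 if (r1 - r0) >= (c1 - c0) else 1
    coords = roi.coords
    order = np.lexsort((coords[:, 1 - axis], coords[:, axis]))
    coords = coords[order]
    n_num = (len(coords) + 1) // 2
    first = ROI.from_coords(coords[:n_num], roi.height, roi.width)
    second = ROI.from_coords(coords[n_num:], roi.height, roi.width)
    return first, second


def normalize_by_split(
    image: RGBImage, roi: ROI, site_id: str = ""
) -> NormalizedFeatureVector:
    """Split normalization for sites without a contralateral reference ROI."""
    first, second = split_roi(roi)
    fv_num = compute_features(image, first, site_id=site_id)
    fv_den = compute_features(image, second, site_id=site_id)
    return normalize_lesion(fv_num, fv_den)
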