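"""Core data model for paired reflectance/autofluorescence oral-site imaging.

A measured oral site consists of a white-light reflectance image and a
blue-excited autofluorescence image, a lesion region of interest (ROI),
and — for sites with an initial clinical impression of *abnormal* — a
contralateral clinically-normal ROI used for normalization plus three
expert observer impressions used for consensus adjudication.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``, row-major.
* Channel intensities are reals in ``[0, 1]``; integer images are rescaled
  by their dtype maximum so features are bit-depth independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Optional, Sequence, Tuple

import numpy as np


class FormatError(ValueError):
    """A file does not conform to the documented schema."""


class ValidationError(ValueError):
    """An object violates a data-model invariant or an operation precondition."""


class Modality(str, Enum):
    REFLECTANCE = "reflectance"
    FLUORESCENCE = "fluorescence"


class ClinicalCategory(IntEnum):
    """Consensus diagnostic category, ordered by increasing severity."""

    NORMAL = 0
    LOW_RISK = 1
    HIGH_RISK = 2
    CANCER = 3

    @property
    def label(self) -> str:
        return _CATEGORY_LABELS[self]

    @classmethod
    def parse(cls, text: str) -> "ClinicalCategory":
        key = str(text).strip().lower().replace(" ", "").replace("_", "").replace("-", "")
        try:
            return _CATEGORY_PARSE[key]
        except KeyError:
            raise FormatError(f"unknown clinical category: {text!r}") from None


_CATEGORY_LABELS = {
    ClinicalCategory.NORMAL: "Normal",
    ClinicalCategory.LOW_RISK: "LowRisk",
    ClinicalCategory.HIGH_RISK: "HighRisk",
    ClinicalCategory.CANCER: "Cancer",
}

_CATEGORY_PARSE = {
    "normal": ClinicalCategory.NORMAL,
    "lowrisk": ClinicalCategory.LOW_RISK,
    "lowriskforneoplasia": ClinicalCategory.LOW_RISK,
    "highrisk": ClinicalCategory.HIGH_RISK,
    "highriskforneoplasia": ClinicalCategory.HIGH_RISK,
    "cancer": ClinicalCategory.CANCER,
}


@dataclass(frozen=True)
class RGBImage:
    """An H x W RGB image with channel values in [0, 1] and a modality tag."""

    pixels: np.ndarray
    modality: Modality

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"expected an (H, W, 3) array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must have H >= 1 and W >= 1")
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("channel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "modality", Modality(self.modality))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_array(cls, arr: np.ndarray, modality: Modality) -> "RGBImage":
        """Build from a raw array, rescaling integer dtypes by their maximum."""
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / float(np.iinfo(arr.dtype).max)
        return cls(arr, modality)

    def scaled(self, factor: float) -> "RGBImage":
        """Return a copy with all intensities multiplied by ``factor`` (clipped)."""
        return RGBImage(np.clip(self.pixels * factor, 0.0, 1.0), self.modality)


@dataclass(frozen=True)
class ROI:
    """A non-empty set of pixels, stored as a boolean membership mask."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValidationError(f"ROI mask must be 2-D, got shape {m.shape}")
        if not m.any():
            raise ValidationError("ROI is empty")
        object.__setattr__(self, "mask", m)

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def coords(self) -> np.ndarray:
        """Member pixel coordinates as an (N, 2) array in row-major order."""
        return np.argwhere(self.mask)

    def bounding_box(self) -> Tuple[int, int, int, int]:
        """(row_min, row_max, col_min, col_max), inclusive."""
        rows, cols = np.nonzero(self.mask)
        return int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())

    @classmethod
    def from_coords(
        cls, coords: Sequence[Tuple[int, int]], height: int, width: int
    ) -> "ROI":
        mask = np.zeros((height, width), dtype=bool)
        for r, c in coords:
            if not (0 <= r < height and 0 <= c < width):
                raise ValidationError(f"ROI coordinate {(r, c)} outside image bounds")
            mask[r, c] = True
        return cls(mask)

    def check_compatible(self, image: RGBImage) -> None:
        if (self.height, self.width) != (image.height, image.width):
            raise ValidationError(
                f"ROI shape {(self.height, self.width)} does not match "
                f"image shape {(image.height, image.width)}"
            )


@dataclass
class SiteRecord:
    """One measured oral site: images, ROIs and clinical metadata.

    Images and ROIs may be held in memory (``*_image`` / ``*_roi`` fields)
    or referenced by path and loaded lazily through the accessor properties.
    Metadata-only records (no images or paths) are permitted so that the
    adjudication protocol can be exercised without pixel data.
    """

    site_id: str
    subject_id: str
    subject_type: str  # {patient, volunteer}
    anatomical_site: str
    initial_impression: str  # {normal, abnormal}
    observer_impressions: Tuple[ClinicalCategory, ...] = ()
    melanosis_visible: bool = False
    osf_visible: bool = False
    reflectance_image: Optional[RGBImage] = None
    fluorescence_image: Optional[RGBImage] = None
    lesion_roi: Optional[ROI] = None
    contralateral_roi: Optional[ROI] = None
    reflectance_path: Optional[str] = None
    fluorescence_path: Optional[str] = None
    lesion_roi_path: Optional[str] = None
    contralateral_roi_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.subject_type not in ("patient", "volunteer"):
            raise ValidationError(
                f"site {self.site_id}: subject_type must be patient or volunteer"
            )
        if self.initial_impression not in ("normal", "abnormal"):
            raise ValidationError(
                f"site {self.site_id}: initial_impression must be normal or abnormal"
            )
        self.observer_impressions = tuple(self.observer_impressions)
        if self.initial_impression == "abnormal":
            if len(self.observer_impressions) != 3:
                raise ValidationError(
                    f"site {self.site_id}: abnormal sites require exactly 3 observer "
                    f"impressions, got {len(self.observer_impressions)}"
                )
            # Image-bearing abnormal records must carry the contralateral ROI
            # used for normalization; metadata-only records are exempt.
            if self._has_pixel_data() and not (
                self.contralateral_roi is not None or self.contralateral_roi_path
            ):
                raise ValidationError(
                    f"site {self.site_id}: abnormal sites require a contralateral ROI"
                )
        else:
            if self.observer_impressions:
                raise ValidationError(
                    f"site {self.site_id}: initially-normal sites must not carry "
                    "observer impressions"
                )

    def _has_pixel_data(self) -> bool:
        return any(
            x is not None
            for x in (
                self.lesion_roi,
                self.lesion_roi_path,
                self.fluorescence_image,
                self.fluorescence_path,
            )
        )

    # -- lazy accessors -------------------------------------------------
    @property
    def reflectance(self) -> RGBImage:
        if self.reflectance_image is None:
            from . import io

            if self.reflectance_path is None:
                raise ValidationError(f"site {self.site_id}: no reflectance image")
            self.reflectance_image = io.load_image(
                self.reflectance_path, Modality.REFLECTANCE
            )
        return self.reflectance_image

    @property
    def fluorescence(self) -> RGBImage:
        if self.fluorescence_image is None:
            from . import io

            if self.fluorescence_path is None:
                raise ValidationError(f"site {self.site_id}: no fluorescence image")
            self.fluorescence_image = io.load_image(
                self.fluorescence_path, Modality.FLUORESCENCE
            )
        return self.fluorescence_image

    @property
    def lesion(self) -> ROI:
        if self.lesion_roi is None:
            from . import io

            if self.lesion_roi_path is None:
                raise ValidationError(f"site {self.site_id}: no lesion ROI")
            img = self.fluorescence
            self.lesion_roi = io.read_roi(self.lesion_roi_path, img.height, img.width)
        return self.lesion_roi

    @property
    def contralateral(self) -> Optional[ROI]:
        if self.contralateral_roi is None and self.contralateral_roi_path:
            from . import io

            img = self.fluorescence
            self.contralateral_roi = io.read_roi(
                self.contralateral_roi_path, img.height, img.width
            )
        return self.contralateral_roi

    def metadata(self) -> dict:
        """Plain-value metadata fields (no pixel data), for tables and manifests."""
        return {
            "site_id": self.site_id,
            "subject_id": self.subject_id,
            "subject_type": self.subject_type,
            "anatomical_site": self.anatomical_site,
            "initial_impression": self.initial_impression,
            "obs1": self.observer_impressions[0].label if self.observer_impressions else "",
            "obs2": self.observer_impressions[1].label if self.observer_impressions else "",
            "obs3": self.observer_impressions[2].label if self.observer_impressions else "",
            "melanosis": int(self.melanosis_visible),
            "osf": int(self.osf_visible),
        }
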