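import numpy as np
import pytest

from oralscreen import (
    ClinicalCategory,
    Modality,
    RGBImage,
    ROI,
    SiteRecord,
)


def const_image(height, width, rgb, modality=Modality.FLUORESCENCE) -> RGBImage:
    """Constant-valued RGB image."""
    px = np.empty((height, width, 3), dtype=float)
    px[:, :] = rgb
    return RGBImage(px, modality)


def random_image(rng, height=8, width=8, low=0.1, high=0.9,
                 modality=Modality.FLUORESCENCE) -> RGBImage:
    """Random image with intensities bounded away from 0 and 1."""
    return RGBImage(rng.uniform(low, high, size=(height, width, 3)), modality)


def full_roi(height, width) -> ROI:
    return ROI(np.ones((height, width), dtype=bool))


def abnormal_record(observers, site_id="s1", melanosis=False, osf=False) -> SiteRecord:
    """Metadata-only abnormal site for adjudication tests."""
    return SiteRecord(
        site_id=site_id,
        subject_id="p1",
        subject_type="patient",
        anatomical_site="buccal mucosa",
        initial_impression="abnormal",
        observer_impressions=tuple(observers),
        melanosis_visible=melanosis,
        osf_visible=osf,
    )


def normal_record(site_id="s1", melanosis=False, osf=False) -> SiteRecord:
    return SiteRecord(
        site_id=site_id,
        subject_id="v1",
        subject_type="volunteer",
        anatomical_site="buccal mucosa",
        initial_impression="normal",
        melanosis_visible=melanosis,
        osf_visible=osf,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


CATEGORIES = list(ClinicalCategory)
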