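"""Synthetic paired reflectance/fluorescence phantoms for pipeline testing.

The clinical images the analysis was designed for are not distributed, so
this module generates image pairs with the optical structure the analysis
assumes:

* Normal mucosa — homogeneous green autofluorescence;
* Low/High Risk — progressive loss of green (and blue) fluorescence in the
  lesion region;
* Cancer — strong green loss plus an orange-red fluorescence gain
  (porphyrin-like);
* melanosis — dark pigment in reflectance and a multiplicative loss of all
  fluorescence channels, without neoplasia;
* OSF (oral submucous fibrosis) — pale, patchy reflectance with preserved
  (slightly increased) green fluorescence.

Noise has two components: independent per-pixel Gaussian noise (clipped to
[0, 1]) and a per-site Gaussian offset on each fluorescence channel's
lesion/normal design factor.  The per-site component is what gives
site-level features their spread — pixel noise alone would vanish when
averaged over an ROI — and it makes the normalized green MFI of a category
approximately N(design factor, site_offset_sd), which yields a closed-form
expected AUC between two categories of Phi(|g1 - g2| / (sigma * sqrt(2))).

All effect magnitudes are package design choices: the source observations
constrain only the directions of the effects and the approximate operating
thresholds.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import io as _io
from .constants import CLINICAL_SITE_COUNTS
from .datamodel import (
    ClinicalCategory,
    Modality,
    RGBImage,
    ROI,
    SiteRecord,
    ValidationError,
)

CATEGORY_ORDER: Tuple[str, ...] = ("Normal", "LowRisk", "HighRisk", "Cancer")
CONFOUNDER_ORDER: Tuple[str, ...] = ("none", "melanosis", "osf")

_ANATOMICAL_SITES = ("buccal mucosa", "lateral tongue", "lip")


@dataclass
class CategoryOpticsParams:
    """Gaussian channel parameters for one category or confounder.

    Fluorescence means/SDs are on the [0, 1] intensity scale.
    ``pigment_attenuation`` multiplies all fluorescence channels (melanosis
    model); ``reflectance_pallor_boost`` is added to the white-light
    reflectance channels (OSF model).
    """

    red_mean: float
    green_mean: float
    blue_mean: float
    red_sd: float = 0.02
    green_sd: float = 0.02
    blue_sd: float = 0.02
    reflectance_rgb_mean: Tuple[float, float, float] = (0.65, 0.45, 0.40)
    pigment_attenuation: float = 1.0
    reflectance_pallor_boost: float = 0.0

    def __post_init__(self) -> None:
        for name in ("red_mean", "green_mean", "blue_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("red_sd", "green_sd", "blue_sd"):
            if getattr(self, name) < 0.0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 < self.pigment_attenuation <= 1.0:
            raise ValidationError("pigment_attenuation must lie in (0, 1]")
        self.reflectance_rgb_mean = tuple(float(v) for v in self.reflectance_rgb_mean)

    @property
    def fluor_means(self) -> np.ndarray:
        return np.array([self.red_mean, self.green_mean, self.blue_mean])

    @property
    def fluor_sds(self) -> np.ndarray:
        return np.array([self.red_sd, self.green_sd, self.blue_sd])


@dataclass
class SyntheticConfig:
    """Full phantom-generator configuration.

    ``counts`` maps (category, confounder) cells to numbers of sites; the
    default composition mirrors the measured clinical dataset (351 sites).
    """

    categories: Dict[str, CategoryOpticsParams]
    confounders: Dict[str, CategoryOpticsParams]
    counts: Dict[Tuple[str, str], int]
    image_size: Tuple[int, int] = (64, 64)
    roi_shape: str = "ellipse"  # {ellipse, rectangle}
    pixel_noise_sd: float = 0.02
    site_offset_sd: float = 0.10
    disagreement_prob: float = 0.20
    all_disagree_prob: float = 0.0
    seed: int = 17

    def __post_init__(self) -> None:
        for cat in CATEGORY_ORDER:
            if cat not in self.categories:
                raise ValidationError(f"missing category params for {cat!r}")
        for key, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"counts must be >= 0, got {n} for {key}")
        if self.roi_shape not in ("ellipse", "rectangle"):
            raise ValidationError(f"unknown roi_shape {self.roi_shape!r}")

    # -- derived quantities ---------------------------------------------
    def design_normalized(self, category: str, confounder: str, channel: str) -> float:
        """Zero-noise design value of the normalized channel MFI."""
        idx = {"red": 0, "green": 1, "blue": 2}[channel]
        eff, _, _ = effective_optics(category, confounder, self)
        normal = self.categories["Normal"].fluor_means
        return float(eff[idx] / normal[idx])

    def design_normalized_rg(self, category: str, confounder: str) -> float:
        """Zero-noise design value of the normalized red/green MFI ratio."""
        eff, _, _ = effective_optics(category, confounder, self)
        normal = self.categories["Normal"].fluor_means
        return float((eff[0] / eff[1]) / (normal[0] / normal[1]))

    def total_sites(self) -> int:
        return sum(self.counts.values())

    # -- copies ----------------------------------------------------------
    def with_noise(self, pixel_sd: float, site_sd: float) -> "SyntheticConfig":
        """Copy with all pixel-level SDs set to ``pixel_sd`` and the per-site
        offset SD set to ``site_sd``."""
        cats = {
            k: dataclasses.replace(v, red_sd=pixel_sd, green_sd=pixel_sd, blue_sd=pixel_sd)
            for k, v in self.categories.items()
        }
        confs = {
            k: dataclasses.replace(v, red_sd=pixel_sd, green_sd=pixel_sd, blue_sd=pixel_sd)
            for k, v in self.confounders.items()
        }
        return dataclasses.replace(
            self,
            categories=cats,
            confounders=confs,
            pixel_noise_sd=pixel_sd,
            site_offset_sd=site_sd,
        )

    def scaled(self, scale: float) -> "SyntheticConfig":
        return dataclasses.replace(self, counts=scale_counts(self.counts, scale))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def params(p: CategoryOpticsParams) -> dict:
            d = dataclasses.asdict(p)
            d["reflectance_rgb_mean"] = list(p.reflectance_rgb_mean)
            return d

        return {
            "categories": {k: params(v) for k, v in self.categories.items()},
            "confounders": {k: params(v) for k, v in self.confounders.items()},
            "counts": {f"{cat}:{conf}": int(n) for (cat, conf), n in self.counts.items()},
            "image_size": list(self.image_size),
            "roi_shape": self.roi_shape,
            "pixel_noise_sd": self.pixel_noise_sd,
            "site_offset_sd": self.site_offset_sd,
            "disagreement_prob": self.disagreement_prob,
            "all_disagree_prob": self.all_disagree_prob,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        def params(d: dict) -> CategoryOpticsParams:
            d = dict(d)
            d["reflectance_rgb_mean"] = tuple(d["reflectance_rgb_mean"])
            return CategoryOpticsParams(**d)

        counts = {}
        for key, n in data["counts"].items():
            cat, conf = key.split(":")
            counts[(cat, conf)] = int(n)
        return cls(
            categories={k: params(v) for k, v in data["categories"].items()},
            confounders={k: params(v) for k, v in data["confounders"].items()},
            counts=counts,
            image_size=tuple(data["image_size"]),
            roi_shape=data["roi_shape"],
            pixel_noise_sd=float(data["pixel_noise_sd"]),
            site_offset_sd=float(data["site_offset_sd"]),
            disagreement_prob=float(data["disagreement_prob"]),
            all_disagree_prob=float(data["all_disagree_prob"]),
            seed=int(data["seed"]),
        )

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 17) -> SyntheticConfig:
    """Default phantom parameters.

    Fluorescence design factors (lesion/normal): green 1.0 / 0.90 / 0.75 /
    0.60 and blue 1.0 / 0.85 / 0.65 / 0.50 across Normal -> Cancer; red is
    flat except a 1.2x gain for Cancer.  The resulting design normalized
    red/green ratios are 1.0, 1.11, 1.33 and 2.0, so the optimal decision
    threshold for that feature falls just above 1.1.  Melanosis attenuates
    all fluorescence channels by 0.55 with a dark reflectance patch; OSF
    preserves fluorescence (green x1.02) under a pale reflectance patch.
    """
    pix = 0.02
    categories = {
        "Normal": CategoryOpticsParams(
            red_mean=0.15, green_mean=0.60, blue_mean=0.30,
            red_sd=pix, green_sd=pix, blue_sd=pix,
            reflectance_rgb_mean=(0.65, 0.45, 0.40),
        ),
        "LowRisk": CategoryOpticsParams(
            red_mean=0.15, green_mean=0.54, blue_mean=0.255,
            red_sd=pix, green_sd=pix, blue_sd=pix,
            reflectance_rgb_mean=(0.66, 0.44, 0.39),
        ),
        "HighRisk": CategoryOpticsParams(
            red_mean=0.15, green_mean=0.45, blue_mean=0.195,
            red_sd=pix, green_sd=pix, blue_sd=pix,
            reflectance_rgb_mean=(0.68, 0.42, 0.38),
        ),
        "Cancer": CategoryOpticsParams(
            red_mean=0.18, green_mean=0.36, blue_mean=0.15,
            red_sd=pix, green_sd=pix, blue_sd=pix,
            reflectance_rgb_mean=(0.70, 0.40, 0.35),
        ),
    }
    confounders = {
        "melanosis": CategoryOpticsParams(
            red_mean=0.15, green_mean=0.60, blue_mean=0.30,
            red_sd=pix, green_sd=pix, blue_sd=pix,
            reflectance_rgb_mean=(0.25, 0.18, 0.15),
            pigment_attenuation=0.55,
        ),
        "osf": CategoryOpticsParams(
            red_mean=0.15, green_mean=0.612, blue_mean=0.30,
            red_sd=pix, green_sd=pix, blue_sd=pix,
            reflectance_rgb_mean=(0.65, 0.45, 0.40),
            reflectance_pallor_boost=0.25,
        ),
    }
    return SyntheticConfig(
        categories=categories,
        confounders=confounders,
        counts=dict(CLINICAL_SITE_COUNTS),
        seed=seed,
    )


def scale_counts(
    counts: Dict[Tuple[str, str], int], scale: float
) -> Dict[Tuple[str, str], int]:
    """Scale cell counts, rounding half-up per cell."""
    if scale <= 0:
        raise ValidationError("scale must be > 0")
    return {key: int(math.floor(n * scale + 0.5)) for key, n in counts.items()}


def effective_optics(
    category: str, confounder: str, config: SyntheticConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lesion-region (fluor_means, fluor_sds, reflectance_means) for a cell."""
    if category not in CATEGORY_ORDER:
        raise ValidationError(f"unknown category {category!r}")
    if confounder not in CONFOUNDER_ORDER:
        raise ValidationError(f"unknown confounder {confounder!r}")
    base = config.categories[category]
    fluor = base.fluor_means.copy()
    sds = base.fluor_sds.copy()
    reflect = np.array(base.reflectance_rgb_mean)
    if confounder == "melanosis":
        mel = config.confounders["melanosis"]
        fluor = fluor * mel.pigment_attenuation
        sds = mel.fluor_sds.copy()
        reflect = np.array(mel.reflectance_rgb_mean)
    elif confounder == "osf":
        osf = config.confounders["osf"]
        # fibrosis preserves autofluorescence regardless of clinical grade
        fluor = osf.fluor_means.copy()
        sds = osf.fluor_sds.copy()
        reflect = np.clip(
            np.array(base.reflectance_rgb_mean) + osf.reflectance_pallor_boost, 0.0, 1.0
        )
    return fluor, sds, reflect


def site_rois(config: SyntheticConfig) -> Tuple[ROI, ROI]:
    """Deterministic lesion and contralateral ROIs for the configured frame."""
    h, w = config.image_size
    if config.roi_shape == "ellipse":
        from skimage.draw import ellipse

        mask_l = np.zeros((h, w), dtype=bool)
        rr, cc = ellipse(h // 2, w // 4, h // 5, w // 8, shape=(h, w))
        mask_l[rr, cc] = True
        mask_c = np.zeros((h, w), dtype=bool)
        rr, cc = ellipse(h // 2, 3 * w // 4, h // 5, w // 8, shape=(h, w))
        mask_c[rr, cc] = True
    else:  # rectangle
        mask_l = np.zeros((h, w), dtype=bool)
        mask_l[h // 3 : 2 * h // 3, w // 8 : 3 * w // 8] = True
        mask_c = np.zeros((h, w), dtype=bool)
        mask_c[h // 3 : 2 * h // 3, w - 3 * w // 8 : w - w // 8] = True
    if mask_l.sum() == 0 or mask_c.sum() == 0:
        raise ValidationError(f"image size {config.image_size} too small for ROIs")
    return ROI(mask_l), ROI(mask_c)


def _draw_observers(
    true: ClinicalCategory, config: SyntheticConfig, rng: np.random.Generator
) -> Tuple[ClinicalCategory, ...]:
    """Three observer impressions: unanimous by default, one adjacent-grade
    deviation with probability ``disagreement_prob``, all-distinct (site
    later excluded) with probability ``all_disagree_prob``."""
    cats = list(ClinicalCategory)
    u = rng.random()
    if u < config.all_disagree_prob:
        others = [c for c in cats if c != true]
        picked = rng.choice(len(others), size=2, replace=False)
        trio = [true, others[picked[0]], others[picked[1]]]
        while trio[1] == trio[2]:  # pragma: no cover - choice is replace=False
            break
    elif u < config.all_disagree_prob + config.disagreement_prob:
        candidates = [c for c in cats if abs(int(c) - int(true)) == 1]
        dev = candidates[int(rng.integers(len(candidates)))]
        trio = [true, true, dev]
    else:
        trio = [true, true, true]
    perm = rng.permutation(3)
    return tuple(trio[i] for i in perm)


def generate_site(
    category: str,
    confounder: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    site_id: str = "site0001",
    subject_id: str = "subj0001",
    anatomical_site: str = "buccal mucosa",
) -> SiteRecord:
    """Generate one site's image pair, ROIs and metadata.

    The lesion ROI carries the category/confounder optics with the per-site
    design-factor offset; everything else in the frame (including the
    contralateral ROI) follows Normal statistics.  Sites of category
    ``Normal`` have an initial impression of normal, a single representative
    ROI and no observer review; all other categories are initially abnormal
    with a contralateral ROI and three observer impressions.
    """
    h, w = config.image_size
    lesion_roi, contra_roi = site_rois(config)
    normal = config.categories["Normal"]
    eff_means, eff_sds, eff_reflect = effective_optics(category, confounder, config)
    design = eff_means / normal.fluor_means
    site_factor = design + rng.normal(0.0, config.site_offset_sd, size=3)
    lesion_means = np.clip(normal.fluor_means * site_factor, 0.0, 1.0)

    fluor = rng.normal(normal.fluor_means, normal.fluor_sds, size=(h, w, 3))
    fluor[lesion_roi.mask] = rng.normal(
        lesion_means, eff_sds, size=(lesion_roi.pixel_count, 3)
    )
    fluor = np.clip(fluor, 0.0, 1.0)

    reflect = rng.normal(
        np.array(normal.reflectance_rgb_mean), config.pixel_noise_sd, size=(h, w, 3)
    )
    reflect[lesion_roi.mask] = rng.normal(
        eff_reflect, config.pixel_noise_sd, size=(lesion_roi.pixel_count, 3)
    )
    reflect = np.clip(reflect, 0.0, 1.0)

    initial_normal = category == "Normal"
    if initial_normal:
        impressions: Tuple[ClinicalCategory, ...] = ()
    else:
        impressions = _draw_observers(ClinicalCategory.parse(category), config, rng)

    return SiteRecord(
        site_id=site_id,
        subject_id=subject_id,
        subject_type="volunteer" if (initial_normal and confounder == "none") else "patient",
        anatomical_site=anatomical_site,
        initial_impression="normal" if initial_normal else "abnormal",
        observer_impressions=impressions,
        melanosis_visible=(confounder == "melanosis"),
        osf_visible=(confounder == "osf"),
        reflectance_image=RGBImage(reflect, Modality.REFLECTANCE),
        fluorescence_image=RGBImage(fluor, Modality.FLUORESCENCE),
        lesion_roi=lesion_roi,
        contralateral_roi=None if initial_normal else contra_roi,
    )


def generate_dataset(
    config: SyntheticConfig, out_dir: Optional[str] = None
) -> List[SiteRecord]:
    """Generate all configured sites (deterministic order and IDs).

    With ``out_dir`` set, writes 8-bit PNG images and masks, the manifest
    CSV (relative paths) and the generator config YAML into that directory.
    """
    rng = np.random.default_rng(config.seed)
    records: List[SiteRecord] = []
    i = 0
    for confounder in CONFOUNDER_ORDER:
        for category in CATEGORY_ORDER:
            for _ in range(config.counts.get((category, confounder), 0)):
                i += 1
                records.append(
                    generate_site(
                        category,
                        confounder,
                        config,
                        rng,
                        site_id=f"site{i:04d}",
                        subject_id=f"subj{i:04d}",
                        anatomical_site=_ANATOMICAL_SITES[i % len(_ANATOMICAL_SITES)],
                    )
                )
    if out_dir is not None:
        _write_dataset(records, config, out_dir)
    return records


def _write_dataset(
    records: List[SiteRecord], config: SyntheticConfig, out_dir: str
) -> None:
    images_dir = os.path.join(out_dir, "images")
    masks_dir = os.path.join(out_dir, "masks")
    os.makedirs(images_dir, exist_ok=True)
    os.makedirs(masks_dir, exist_ok=True)
    path_rows = []
    for rec in records:
        sid = rec.site_id
        paths = {
            "reflectance_path": f"images/{sid}_refl.png",
            "fluorescence_path": f"images/{sid}_fluor.png",
            "lesion_roi_path": f"masks/{sid}_lesion.png",
            "contralateral_roi_path": (
                f"masks/{sid}_contra.png" if rec.contralateral_roi is not None else ""
            ),
        }
        _io.save_image_png(rec.reflectance_image, os.path.join(out_dir, paths["reflectance_path"]))
        _io.save_image_png(rec.fluorescence_image, os.path.join(out_dir, paths["fluorescence_path"]))
        _io.save_roi_png(rec.lesion_roi, os.path.join(out_dir, paths["lesion_roi_path"]))
        if rec.contralateral_roi is not None:
            _io.save_roi_png(
                rec.contralateral_roi, os.path.join(out_dir, paths["contralateral_roi_path"])
            )
        path_rows.append(paths)
    _io.write_manifest(records, os.path.join(out_dir, "manifest.csv"), paths=path_rows)
    config.save(os.path.join(out_dir, "config.yaml"))
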