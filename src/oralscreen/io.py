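"""Readers and writers for images, ROIs, site manifests and feature tables.

File formats
------------
* Images: PNG or TIFF, RGB (an alpha channel is ignored with a warning).
* ROI: either a single-channel mask image (nonzero = member) or a JSON
  polygon ``{"vertices": [[row, col], ...]}`` rasterized by even-odd fill
  including boundary pixels.
* Manifest: UTF-8 CSV with a required header (see ``MANIFEST_COLUMNS``).
  Image/ROI paths are resolved relative to the manifest's directory.
* Feature table: CSV, one row per site, floats at 6 significant digits.
"""

from __future__ import annotations

import csv
import json
import os
import warnings
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .datamodel import (
    ClinicalCategory,
    FormatError,
    Modality,
    RGBImage,
    ROI,
    SiteRecord,
    ValidationError,
)

MANIFEST_COLUMNS = [
    "site_id",
    "subject_id",
    "subject_type",
    "anatomical_site",
    "initial_impression",
    "obs1",
    "obs2",
    "obs3",
    "melanosis",
    "osf",
    "reflectance_path",
    "fluorescence_path",
    "lesion_roi_path",
    "contralateral_roi_path",
]

_BOOL_VALUES = {"0": False, "1": True, "true": True, "false": False}


def _parse_bool(text: str, column: str, site_id: str) -> bool:
    key = str(text).strip().lower()
    if key not in _BOOL_VALUES:
        raise FormatError(
            f"site {site_id}: column {column} must be one of 0/1/true/false, "
            f"got {text!r}"
        )
    return _BOOL_VALUES[key]


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def load_image(path: str, modality: Modality) -> RGBImage:
    """Load a PNG/TIFF image as an RGBImage, rescaling by the dtype maximum."""
    try:
        with Image.open(path) as im:
            if im.mode in ("RGBA", "LA", "PA"):
                warnings.warn(
                    f"{path}: alpha channel ignored", UserWarning, stacklevel=2
                )
                im = im.convert("RGB")
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        warnings.warn(f"{path}: alpha channel ignored", UserWarning, stacklevel=2)
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return RGBImage.from_array(arr, modality)


def save_image_png(image: RGBImage, path: str) -> None:
    """Write an RGBImage as an 8-bit PNG."""
    arr = np.clip(np.rint(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def _rasterize_polygon(vertices: Sequence[Sequence[float]], height: int, width: int) -> np.ndarray:
    from skimage.draw import polygon, polygon_perimeter

    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValidationError("polygon needs at least 3 (row, col) vertices")
    if (
        verts[:, 0].min() < 0
        or verts[:, 0].max() > height - 1
        or verts[:, 1].min() < 0
        or verts[:, 1].max() > width - 1
    ):
        raise ValidationError("polygon vertex outside image bounds")
    mask = np.zeros((height, width), dtype=bool)
    rr, cc = polygon(verts[:, 0], verts[:, 1], shape=(height, width))
    mask[rr, cc] = True
    rr, cc = polygon_perimeter(verts[:, 0], verts[:, 1], shape=(height, width))
    mask[rr, cc] = True
    return mask


def read_roi(path: str, height: int, width: int) -> ROI:
    """Read an ROI from a mask image or a JSON polygon file.

    The target image dimensions are required so the mask can be validated
    against the image it will be applied to.
    """
    if str(path).lower().endswith(".json"):
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        if "vertices" not in payload:
            raise FormatError(f"{path}: polygon file must contain 'vertices'")
        mask = _rasterize_polygon(payload["vertices"], height, width)
    else:
        with Image.open(path) as im:
            arr = np.asarray(im)
        if arr.ndim == 3:
            arr = arr.any(axis=2)
        mask = np.asarray(arr) != 0
        if mask.shape != (height, width):
            raise ValidationError(
                f"{path}: mask shape {mask.shape} does not match image "
                f"shape {(height, width)}"
            )
    if not mask.any():
        raise ValidationError(f"{path}: ROI is empty")
    return ROI(mask)


def save_roi_png(roi: ROI, path: str) -> None:
    """Write an ROI as an 8-bit mask PNG (255 = member)."""
    arr = (roi.mask.astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path, format="PNG")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def read_manifest(path: str) -> List[SiteRecord]:
    """Read a site manifest CSV into SiteRecords with lazily-loadable images."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in MANIFEST_COLUMNS:
        if column not in df.columns:
            raise FormatError(f"manifest {path}: missing required column {column!r}")
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> Optional[str]:
        p = p.strip()
        if not p:
            return None
        return p if os.path.isabs(p) else os.path.join(base, p)

    records: List[SiteRecord] = []
    for _, row in df.iterrows():
        site_id = row["site_id"]
        initial = row["initial_impression"].strip().lower()
        obs_raw = [row["obs1"].strip(), row["obs2"].strip(), row["obs3"].strip()]
        if initial == "abnormal":
            if any(not o for o in obs_raw):
                raise ValidationError(
                    f"site {site_id}: abnormal sites require 3 observer impressions"
                )
            impressions = tuple(ClinicalCategory.parse(o) for o in obs_raw)
        else:
            if any(obs_raw):
                raise ValidationError(
                    f"site {site_id}: initially-normal sites must have empty "
                    "observer columns"
                )
            impressions = ()
        records.append(
            SiteRecord(
                site_id=site_id,
                subject_id=row["subject_id"],
                subject_type=row["subject_type"].strip().lower(),
                anatomical_site=row["anatomical_site"],
                initial_impression=initial,
                observer_impressions=impressions,
                melanosis_visible=_parse_bool(row["melanosis"], "melanosis", site_id),
                osf_visible=_parse_bool(row["osf"], "osf", site_id),
                reflectance_path=resolve(row["reflectance_path"]),
                fluorescence_path=resolve(row["fluorescence_path"]),
                lesion_roi_path=resolve(row["lesion_roi_path"]),
                contralateral_roi_path=resolve(row["contralateral_roi_path"]),
            )
        )
    return records


def write_manifest(
    records: Sequence[SiteRecord], path: str, paths: Optional[Sequence[Mapping[str, str]]] = None
) -> None:
    """Write a manifest CSV.

    ``paths`` optionally supplies per-record file paths (e.g. relative paths
    for a dataset directory); otherwise the records' own path fields are used.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        for i, rec in enumerate(records):
            row = rec.metadata()
            if paths is not None:
                row.update(paths[i])
            else:
                row.update(
                    {
                        "reflectance_path": rec.reflectance_path or "",
                        "fluorescence_path": rec.fluorescence_path or "",
                        "lesion_roi_path": rec.lesion_roi_path or "",
                        "contralateral_roi_path": rec.contralateral_roi_path or "",
                    }
                )
            writer.writerow(row)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def default_feature_table_columns() -> List[str]:
    from .features import FEATURE_FIELDS

    meta = [
        "site_id",
        "subject_id",
        "subject_type",
        "anatomical_site",
        "initial_impression",
        "melanosis",
        "osf",
    ]
    blocks = []
    for prefix in ("fluor_", "norm_", "refl_", "norm_refl_"):
        blocks.extend(prefix + f for f in FEATURE_FIELDS)
    return meta + blocks


def write_feature_table(
    rows: Sequence[Mapping[str, object]],
    path: str,
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write per-site feature rows to CSV with a deterministic column order.

    Floats are written at 6 significant digits. An empty row list produces a
    header-only file.
    """
    if columns is None:
        columns = list(rows[0].keys()) if rows else default_feature_table_columns()
    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, index=False, float_format="%.6g")


def read_feature_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True)
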