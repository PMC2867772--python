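"""Pipeline orchestration: generate -> extract -> adjudicate -> classify -> report.

Each stage consumes and produces the documented file formats (manifest CSV,
feature CSV, consensus CSV, report JSON), so stages can run independently
and an end-to-end run is exactly the composition of the stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as _io
from .adjudication import (
    ConsensusStatus,
    adjudicate,
    binarize,
)
from .classification import (
    CLOSEST_TO_IDEAL,
    ROCCurve,
    fit_single_feature,
    rank_features,
)
from .constants import (
    EXTERNAL_RG_THRESHOLD,
    REFERENCE_OPERATING_POINTS,
    REFERENCE_TOP5_AUC,
)
from .datamodel import SiteRecord, ValidationError
from .features import (
    FEATURE_FIELDS,
    compute_features,
    normalize_by_split,
    normalize_lesion,
)
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("oralscreen")

#: Default candidate features: the normalized fluorescence metrics.
#: Reflectance metrics are computed and reported in the feature table but
#: excluded from the default candidate set.
DEFAULT_CANDIDATE_FEATURES: Tuple[str, ...] = tuple("norm_" + f for f in FEATURE_FIELDS)


@dataclass
class RunConfig:
    """End-to-end run settings; exactly one of manifest/synthetic is set."""

    out_dir: str
    manifest: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    features: Optional[Sequence[str]] = None
    melanosis: str = "exclude"  # {exclude, include}
    qpoint_rule: str = CLOSEST_TO_IDEAL
    seed: Optional[int] = None
    log_level: str = "INFO"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.synthetic is None):
            raise ValidationError(
                "exactly one of a manifest path or a synthetic config is required"
            )
        if self.melanosis not in ("exclude", "include"):
            raise ValidationError("melanosis mode must be exclude or include")


# ---------------------------------------------------------------------------
# in-memory building blocks
# ---------------------------------------------------------------------------

def feature_row(record: SiteRecord) -> Dict[str, object]:
    """Compute the full feature-table row for one site.

    Fluorescence and reflectance metrics are computed over the lesion ROI;
    normalization uses the contralateral ROI when present, otherwise the
    split-ROI rule.
    """
    fluor = record.fluorescence
    refl = record.reflectance
    roi = record.lesion
    fv_fluor = compute_features(fluor, roi, site_id=record.site_id)
    fv_refl = compute_features(refl, roi, site_id=record.site_id)
    contra = record.contralateral
    if contra is not None:
        nf = normalize_lesion(fv_fluor, compute_features(fluor, contra, site_id=record.site_id))
        nr = normalize_lesion(fv_refl, compute_features(refl, contra, site_id=record.site_id))
    else:
        nf = normalize_by_split(fluor, roi, site_id=record.site_id)
        nr = normalize_by_split(refl, roi, site_id=record.site_id)
    row: Dict[str, object] = {
        "site_id": record.site_id,
        "subject_id": record.subject_id,
        "subject_type": record.subject_type,
        "anatomical_site": record.anatomical_site,
        "initial_impression": record.initial_impression,
        "melanosis": int(record.melanosis_visible),
        "osf": int(record.osf_visible),
    }
    for prefix, vec in (
        ("fluor_", fv_fluor),
        ("norm_", nf),
        ("refl_", fv_refl),
        ("norm_refl_", nr),
    ):
        for name, value in vec.as_dict().items():
            row[prefix + name] = value
    return row


def extract_feature_frame(records: Sequence[SiteRecord]) -> pd.DataFrame:
    rows = [feature_row(rec) for rec in records]
    return pd.DataFrame(rows, columns=_io.default_feature_table_columns())


def consensus_frame(
    records: Sequence[SiteRecord], features: pd.DataFrame
) -> pd.DataFrame:
    """Append consensus columns to a feature table (joined on site_id)."""
    cons = []
    for rec in records:
        result = adjudicate(rec)
        assigned = result.status is ConsensusStatus.ASSIGNED
        cons.append(
            {
                "site_id": rec.site_id,
                "consensus_status": result.status.value,
                "consensus_category": result.category.label if assigned else "",
                "agreement": result.agreement.value if assigned else "",
                "binary_label": binarize(result.category).value if assigned else "",
            }
        )
    cons_df = pd.DataFrame(cons)
    return features.merge(cons_df, on="site_id", how="left", validate="one_to_one")


def classify_frame(
    df: pd.DataFrame,
    feature_names: Optional[Sequence[str]] = None,
    melanosis: str = "exclude",
    qpoint_rule: str = CLOSEST_TO_IDEAL,
) -> Tuple[dict, pd.DataFrame, Dict[str, ROCCurve]]:
    """Filter a consensus table, fit per-feature classifiers, build the report.

    Returns (report dict, ranking table, {feature: ROCCurve}).
    """
    if feature_names is None:
        feature_names = list(DEFAULT_CANDIDATE_FEATURES)
    n_in = len(df)
    assigned = df["consensus_status"] == ConsensusStatus.ASSIGNED.value
    n_excluded_disagreement = int((~assigned).sum())
    work = df[assigned]
    if melanosis == "exclude":
        mel = work["melanosis"].astype(int) == 1
        n_excluded_melanosis = int(mel.sum())
        work = work[~mel]
    elif melanosis == "include":
        n_excluded_melanosis = 0
    else:
        raise ValidationError("melanosis mode must be exclude or include")
    n_analyzed = len(work)
    labels = work["binary_label"].tolist()
    site_ids = work["site_id"].tolist()
    n_neo = sum(1 for lab in labels if lab == "neoplastic")

    feature_results: Dict[str, dict] = {}
    curves: Dict[str, ROCCurve] = {}
    table = {name: work[name].to_numpy(dtype=float) for name in feature_names}
    for name in feature_names:
        model, curve = fit_single_feature(
            table[name], labels, feature_name=name,
            qpoint_rule=qpoint_rule, site_ids=site_ids,
        )
        curves[name] = curve
        feature_results[name] = {
            "auc": float(curve.auc),
            "direction": model.direction,
            "q_threshold": float(model.threshold),
            "sensitivity": float(model.sensitivity),
            "specificity": float(model.specificity),
            "n_used": int(np.isfinite(table[name]).sum()),
        }
    ranking = rank_features(table, labels, feature_names, qpoint_rule=qpoint_rule)
    report = {
        "counts": {
            "n_in": n_in,
            "n_excluded_disagreement": n_excluded_disagreement,
            "n_excluded_melanosis": n_excluded_melanosis,
            "n_analyzed": n_analyzed,
            "n_neoplastic": n_neo,
            "n_non_neoplastic": n_analyzed - n_neo,
        },
        "settings": {"melanosis": melanosis, "qpoint_rule": qpoint_rule},
        "features": feature_results,
        "ranking": [
            {"feature": str(r["feature"]), "auc": float(r["auc"])}
            for _, r in ranking.iterrows()
        ],
        "reference": {
            "operating_points": REFERENCE_OPERATING_POINTS,
            "top5_auc": REFERENCE_TOP5_AUC,
            "external_rg_threshold": EXTERNAL_RG_THRESHOLD,
            "note": (
                "Operating points and AUCs measured on the original clinical "
                "dataset; documented for comparison, not reproducible from "
                "synthetic phantoms."
            ),
        },
    }
    return report, ranking, curves


# ---------------------------------------------------------------------------
# file-level stages
# ---------------------------------------------------------------------------

def stage_simulate(config: SyntheticConfig, data_dir: str) -> str:
    """Generate a synthetic dataset on disk; returns the manifest path."""
    generate_dataset(config, out_dir=data_dir)
    return os.path.join(data_dir, "manifest.csv")


def stage_extract(manifest_path: str, features_csv: str) -> None:
    records = _io.read_manifest(manifest_path)
    df = extract_feature_frame(records)
    _io.write_feature_table(
        df.to_dict("records"), features_csv, columns=df.columns
    )


def stage_adjudicate(manifest_path: str, features_csv: str, consensus_csv: str) -> None:
    records = _io.read_manifest(manifest_path)
    features = _io.read_feature_table(features_csv)
    df = consensus_frame(records, features)
    df.to_csv(consensus_csv, index=False, float_format="%.6g")


def stage_classify(
    consensus_csv: str,
    out_dir: str,
    feature_names: Optional[Sequence[str]] = None,
    melanosis: str = "exclude",
    qpoint_rule: str = CLOSEST_TO_IDEAL,
) -> dict:
    """Classify a consensus table; writes report.json, ranking.csv, roc_*.csv."""
    with open(consensus_csv, "rb") as fh:
        input_digest = hashlib.sha256(fh.read()).hexdigest()
    df = _io.read_feature_table(consensus_csv)
    report, ranking, curves = classify_frame(
        df, feature_names=feature_names, melanosis=melanosis, qpoint_rule=qpoint_rule
    )
    report["inputs_sha256"] = input_digest
    os.makedirs(out_dir, exist_ok=True)
    ranking.to_csv(os.path.join(out_dir, "ranking.csv"), index=False, float_format="%.6g")
    for name, curve in curves.items():
        pd.DataFrame(
            {
                "threshold": curve.thresholds,
                "sensitivity": curve.sensitivity,
                "specificity": curve.specificity,
            }
        ).to_csv(os.path.join(out_dir, f"roc_{name}.csv"), index=False, float_format="%.6g")
    with open(os.path.join(out_dir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def stage_report(
    report_json: str,
    out_dir: str,
    consensus_csv: Optional[str] = None,
    plots: bool = False,
) -> str:
    """Render a human-readable summary (and optional figures) from a report."""
    with open(report_json, "r", encoding="utf-8") as fh:
        report = json.load(fh)
    os.makedirs(out_dir, exist_ok=True)
    lines = ["Feature ranking by AUC", "", f"{'Feature':<28}AUC"]
    for entry in report["ranking"][:5]:
        lines.append(f"{entry['feature']:<28}{entry['auc']:.2f}")
    counts = report["counts"]
    lines += [
        "",
        f"sites in: {counts['n_in']}",
        f"excluded (observer disagreement): {counts['n_excluded_disagreement']}",
        f"excluded (melanosis): {counts['n_excluded_melanosis']}",
        f"analyzed: {counts['n_analyzed']} "
        f"({counts['n_neoplastic']} neoplastic / {counts['n_non_neoplastic']} non-neoplastic)",
    ]
    summary_path = os.path.join(out_dir, "summary.txt")
    with open(summary_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    if plots and consensus_csv is not None:
        _make_plots(report, consensus_csv, out_dir)
    return summary_path


def _make_plots(report: dict, consensus_csv: str, out_dir: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = _io.read_feature_table(consensus_csv)
    assigned = df[df["consensus_status"] == "assigned"]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    order = ["Normal", "LowRisk", "HighRisk", "Cancer"]
    for i, cat in enumerate(order):
        vals = assigned.loc[assigned["consensus_category"] == cat, "norm_mfi_b"]
        axes[0].scatter(np.full(len(vals), i), vals, s=12, alpha=0.6)
    axes[0].set_xticks(range(len(order)), order)
    axes[0].set_ylabel("normalized blue MFI")
    roc_path = os.path.join(out_dir, "roc_norm_mfi_b.csv")
    if os.path.exists(roc_path):
        roc = pd.read_csv(roc_path)
        fpr = 1.0 - roc["specificity"]
        idx = np.argsort(fpr)
        axes[1].plot(fpr.to_numpy()[idx], roc["sensitivity"].to_numpy()[idx])
        axes[1].set_xlabel("1 - specificity")
        axes[1].set_ylabel("sensitivity")
        axes[1].set_title(f"norm_mfi_b AUC = {report['features']['norm_mfi_b']['auc']:.2f}")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "figures.png"), dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the classification report dict.

    Writes under ``cfg.out_dir``: a dataset directory (synthetic runs),
    features.csv, consensus.csv, ranking.csv, per-feature ROC CSVs,
    report.json, summary.txt and run.log.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.out_dir, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(cfg.log_level.upper())
    try:
        if cfg.synthetic is not None:
            config = cfg.synthetic
            if cfg.seed is not None:
                import dataclasses

                config = dataclasses.replace(config, seed=cfg.seed)
            digest = hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest()
            logger.info("synthetic run: seed=%s config_sha256=%s", config.seed, digest)
            manifest = stage_simulate(config, os.path.join(cfg.out_dir, "data"))
        else:
            manifest = cfg.manifest
            with open(manifest, "rb") as fh:
                digest = hashlib.sha256(fh.read()).hexdigest()
            logger.info("manifest run: manifest_sha256=%s", digest)
        features_csv = os.path.join(cfg.out_dir, "features.csv")
        consensus_csv = os.path.join(cfg.out_dir, "consensus.csv")
        stage_extract(manifest, features_csv)
        stage_adjudicate(manifest, features_csv, consensus_csv)
        report = stage_classify(
            consensus_csv,
            cfg.out_dir,
            feature_names=cfg.features,
            melanosis=cfg.melanosis,
            qpoint_rule=cfg.qpoint_rule,
        )
        counts = report["counts"]
        logger.info(
            "counts: in=%d excluded_disagreement=%d excluded_melanosis=%d analyzed=%d",
            counts["n_in"],
            counts["n_excluded_disagreement"],
            counts["n_excluded_melanosis"],
            counts["n_analyzed"],
        )
        stage_report(
            os.path.join(cfg.out_dir, "report.json"),
            cfg.out_dir,
            consensus_csv=consensus_csv,
            plots=cfg.make_plots,
        )
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
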