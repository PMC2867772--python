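"""Single-feature threshold classification, ROC sweep, AUC and Q-point.

A binary classifier on one image feature is an exhaustive threshold sweep:
the threshold runs from below the minimum to above the maximum observed
value, and at each threshold sensitivity and specificity are computed
against the consensus labels.  With a single input and equal-variance
class assumptions a univariate Fisher discriminant is order-preserving in
the feature, so this sweep traces the same ROC the discriminant would.

The area under the ROC curve (AUC) is computed by the trapezoidal rule
over (FPR, TPR); it equals the Mann-Whitney concordant-pair probability
with ties counted 1/2.  The reported operating point is the Q-point, the
curve point closest in Euclidean distance to perfect classification
(FPR, TPR) = (0, 1); an alternative sensitivity = specificity rule is
available.  Multi-feature models use a Fisher linear discriminant with
pooled within-class covariance and a small ridge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .adjudication import BinaryLabel
from .datamodel import ValidationError

HIGH_IS_NEOPLASTIC = "high_is_neoplastic"
LOW_IS_NEOPLASTIC = "low_is_neoplastic"

CLOSEST_TO_IDEAL = "closest_to_ideal"
SENS_EQ_SPEC = "sens_eq_spec"


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ROCCurve:
    """Ordered ROC operating points with trapezoidal AUC.

    ``thresholds`` ascend and include sentinels below the minimum and above
    the maximum score, so the curve always contains the (sens, spec) = (1, 0)
    and (0, 1) endpoints.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str

    def points(self) -> List[OperatingPoint]:
        return [
            OperatingPoint(float(t), float(se), float(sp))
            for t, se, sp in zip(self.thresholds, self.sensitivity, self.specificity)
        ]


@dataclass(frozen=True)
class ClassifierModel:
    """A fitted single-feature threshold rule.

    ``predict`` labels a score neoplastic when it falls on the neoplastic
    side of the threshold (scores exactly at the threshold are positive).
    """

    feature_name: str
    threshold: float
    direction: str
    sensitivity: float = math.nan
    specificity: float = math.nan

    def predict(self, scores: Sequence[float]) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if self.direction == HIGH_IS_NEOPLASTIC:
            return scores >= self.threshold
        return scores <= self.threshold


def as_positive_mask(labels: Sequence) -> np.ndarray:
    """Coerce labels (BinaryLabel, str, bool, 0/1) to a neoplastic mask."""
    out = []
    for lab in labels:
        if isinstance(lab, BinaryLabel):
            out.append(lab is BinaryLabel.NEOPLASTIC)
        elif isinstance(lab, str):
            key = lab.strip().lower()
            if key not in ("neoplastic", "non_neoplastic"):
                raise ValidationError(f"unknown binary label {lab!r}")
            out.append(key == "neoplastic")
        elif isinstance(lab, (bool, np.bool_, int, np.integer)):
            out.append(bool(lab))
        else:
            raise ValidationError(f"cannot interpret label {lab!r}")
    return np.asarray(out, dtype=bool)


def roc_sweep(
    scores: Sequence[float],
    labels: Sequence,
    direction: str = HIGH_IS_NEOPLASTIC,
    site_ids: Optional[Sequence[str]] = None,
) -> ROCCurve:
    """Exhaustive threshold sweep over the observed score range.

    For ``high_is_neoplastic`` a site is predicted neoplastic when its score
    is >= the threshold (<= for ``low_is_neoplastic``).
    """
    if direction not in (HIGH_IS_NEOPLASTIC, LOW_IS_NEOPLASTIC):
        raise ValidationError(f"unknown direction {direction!r}")
    scores = np.asarray(scores, dtype=float)
    pos = as_positive_mask(labels)
    if scores.shape[0] != pos.shape[0]:
        raise ValidationError("scores and labels must have equal length")
    bad = ~np.isfinite(scores)
    if bad.any():
        idx = int(np.argmax(bad))
        who = site_ids[idx] if site_ids is not None else f"index {idx}"
        raise ValidationError(f"non-finite score for site {who}")
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both neoplastic and non-neoplastic labels are required")

    uniq = np.unique(scores)
    thresholds = np.concatenate(([uniq[0] - 1.0], uniq, [uniq[-1] + 1.0]))
    pos_sorted = np.sort(scores[pos])
    neg_sorted = np.sort(scores[~pos])
    if direction == HIGH_IS_NEOPLASTIC:
        # count of scores >= t
        tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
        fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    else:
        # count of scores <= t
        tp = np.searchsorted(pos_sorted, thresholds, side="right")
        fp = np.searchsorted(neg_sorted, thresholds, side="right")
    sens = tp / n_pos
    fpr = fp / n_neg
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=1.0 - fpr,
        auc=auc,
        direction=direction,
    )


def q_point(curve: ROCCurve, rule: str = CLOSEST_TO_IDEAL) -> OperatingPoint:
    """Select the reported operating point on an ROC curve.

    ``closest_to_ideal`` (default) minimizes the Euclidean distance to
    (FPR, TPR) = (0, 1); ``sens_eq_spec`` minimizes |sens - spec|.  Ties are
    broken by higher sensitivity, then lower threshold.
    """
    sens = curve.sensitivity
    spec = curve.specificity
    if rule == CLOSEST_TO_IDEAL:
        objective = (1.0 - spec) ** 2 + (1.0 - sens) ** 2
    elif rule == SENS_EQ_SPEC:
        objective = np.abs(sens - spec)
    else:
        raise ValidationError(f"unknown Q-point rule {rule!r}")
    # lexicographic: smallest objective, then largest sensitivity, then
    # smallest threshold
    order = np.lexsort((curve.thresholds, -sens, objective))
    best = order[0]
    return OperatingPoint(
        float(curve.thresholds[best]), float(sens[best]), float(spec[best])
    )


def _refine_threshold(curve: ROCCurve, threshold: float) -> float:
    """Move a data-valued threshold to the midpoint of its decision interval.

    Any threshold in the half-open interval between two adjacent distinct
    scores yields the same confusion matrix; the midpoint places the stored
    decision boundary strictly between the neighbouring score values.
    """
    inner = curve.thresholds[1:-1]  # the observed unique scores
    idx = int(np.searchsorted(inner, threshold))
    if idx >= len(inner) or inner[idx] != threshold:
        return float(threshold)  # sentinel threshold; keep as-is
    if curve.direction == HIGH_IS_NEOPLASTIC:
        if idx == 0:
            return float(threshold)
        return float(0.5 * (inner[idx - 1] + inner[idx]))
    if idx == len(inner) - 1:
        return float(threshold)
    return float(0.5 * (inner[idx] + inner[idx + 1]))


def fit_single_feature(
    values: Sequence[float],
    labels: Sequence,
    feature_name: str = "feature",
    qpoint_rule: str = CLOSEST_TO_IDEAL,
    site_ids: Optional[Sequence[str]] = None,
) -> Tuple[ClassifierModel, ROCCurve]:
    """Fit a single-feature threshold classifier in-sample.

    The sweep direction is chosen so the class with the higher mean score is
    predicted positive.  Sites with undefined (NaN) feature values are
    dropped with a warning.  The model threshold is the Q-point threshold,
    refined to the midpoint of its decision interval; training and
    evaluation use the same data.
    """
    values = np.asarray(values, dtype=float)
    pos = as_positive_mask(labels)
    defined = np.isfinite(values)
    if not defined.all():
        dropped = int((~defined).sum())
        warnings.warn(
            f"{feature_name}: dropped {dropped} site(s) with undefined values",
            UserWarning,
            stacklevel=2,
        )
        if site_ids is not None:
            site_ids = [s for s, d in zip(site_ids, defined) if d]
        values, pos = values[defined], pos[defined]
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValidationError("both classes required after dropping undefined values")
    mean_pos = values[pos].mean()
    mean_neg = values[~pos].mean()
    if mean_pos == mean_neg:
        warnings.warn(
            f"{feature_name}: class means are equal; feature carries no "
            "discriminative signal",
            UserWarning,
            stacklevel=2,
        )
    direction = HIGH_IS_NEOPLASTIC if mean_pos >= mean_neg else LOW_IS_NEOPLASTIC
    curve = roc_sweep(values, pos, direction=direction, site_ids=site_ids)
    op = q_point(curve, rule=qpoint_rule)
    model = ClassifierModel(
        feature_name=feature_name,
        threshold=_refine_threshold(curve, op.threshold),
        direction=direction,
        sensitivity=op.sensitivity,
        specificity=op.specificity,
    )
    return model, curve


def rank_features(
    feature_table: Mapping[str, Sequence[float]],
    labels: Sequence,
    feature_names: Optional[Sequence[str]] = None,
    qpoint_rule: str = CLOSEST_TO_IDEAL,
) -> pd.DataFrame:
    """Rank candidate features by in-sample AUC (ties broken alphabetically).

    Returns a DataFrame with columns ``feature``, ``auc``, ``direction``,
    ``q_threshold``, ``sensitivity``, ``specificity`` sorted by descending
    AUC.
    """
    if feature_names is None:
        feature_names = list(feature_table.keys())
    rows = []
    for name in feature_names:
        model, curve = fit_single_feature(
            feature_table[name], labels, feature_name=name, qpoint_rule=qpoint_rule
        )
        rows.append(
            {
                "feature": name,
                "auc": curve.auc,
                "direction": model.direction,
                "q_threshold": model.threshold,
                "sensitivity": model.sensitivity,
                "specificity": model.specificity,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["auc", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def fit_multi_feature(
    X: np.ndarray,
    labels: Sequence,
    feature_names: Optional[Sequence[str]] = None,
    ridge: float = 1e-6,
) -> Tuple[np.ndarray, ROCCurve]:
    """Fisher linear discriminant over >= 2 features.

    Projects onto w = (S_w + ridge I)^-1 (mu_pos - mu_neg), where S_w is the
    pooled within-class covariance, then sweeps the projected scores.  The
    projection points toward the neoplastic mean, so higher projected scores
    are neoplastic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("fit_multi_feature requires an (n, p>=2) matrix")
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix contains undefined values")
    pos = as_positive_mask(labels)
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValidationError("both classes required")
    X1, X0 = X[pos], X[~pos]
    mu1, mu0 = X1.mean(axis=0), X0.mean(axis=0)
    n = X.shape[0]
    scatter = (X1 - mu1).T @ (X1 - mu1) + (X0 - mu0).T @ (X0 - mu0)
    pooled = scatter / max(n - 2, 1)
    pooled = pooled + ridge * np.eye(X.shape[1])
    try:
        w = np.linalg.solve(pooled, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular pooled covariance: {exc}") from exc
    if not np.all(np.isfinite(w)):
        raise ValidationError("singular pooled covariance (non-finite weights)")
    scores = X @ w
    curve = roc_sweep(scores, pos, direction=HIGH_IS_NEOPLASTIC)
    return w, curve
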