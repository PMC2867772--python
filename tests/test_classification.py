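"""ROC sweep, AUC, Q-point selection and discriminant fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oralscreen import (
    ROCCurve,
    ValidationError,
    fit_multi_feature,
    fit_single_feature,
    q_point,
    rank_features,
    roc_sweep,
)
from oralscreen.classification import (
    CLOSEST_TO_IDEAL,
    HIGH_IS_NEOPLASTIC,
    LOW_IS_NEOPLASTIC,
    SENS_EQ_SPEC,
)

NEO, NON = "neoplastic", "non_neoplastic"


def mann_whitney_auc(scores, labels, direction=HIGH_IS_NEOPLASTIC):
    """Concordant-pair oracle: P(neoplastic score beats non-neoplastic), ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == NEO]
    neg = [s for s, l in zip(scores, labels) if l == NON]
    total = 0.0
    for p in pos:
        for n in neg:
            better = p > n if direction == HIGH_IS_NEOPLASTIC else p < n
            total += 1.0 if better else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROCSweep:
    def test_perfect_separation_gives_auc_one(self):
        curve = roc_sweep([0.9, 0.8, 0.4, 0.3], [NEO, NEO, NON, NON])
        assert curve.auc == pytest.approx(1.0)

    def test_interleaved_scores_auc_three_quarters(self):
        curve = roc_sweep([1, 2, 3, 4], [NON, NEO, NON, NEO])
        assert curve.auc == pytest.approx(0.75)

    def test_constant_scores_give_diagonal_auc_half(self):
        curve = roc_sweep([1.0, 1.0, 1.0, 1.0], [NEO, NON, NEO, NON])
        assert curve.auc == pytest.approx(0.5)

    def test_endpoints_present(self):
        curve = roc_sweep([0.1, 0.5, 0.9], [NON, NEO, NEO])
        pts = {(round(p.sensitivity, 9), round(p.specificity, 9)) for p in curve.points()}
        assert (1.0, 0.0) in pts and (0.0, 1.0) in pts

    def test_curve_monotone_after_sorting_by_fpr(self, rng):
        scores = rng.normal(size=40)
        labels = [NEO if rng.random() < 0.4 else NON for _ in range(40)]
        labels[0], labels[1] = NEO, NON
        curve = roc_sweep(scores, labels)
        fpr = 1.0 - curve.specificity
        order = np.lexsort((curve.sensitivity, fpr))
        assert np.all(np.diff(fpr[order]) >= 0)
        assert np.all(np.diff(curve.sensitivity[order]) >= 0)

    def test_direction_reversal_complements_auc(self, rng):
        scores = rng.normal(size=30)
        labels = [NEO] * 12 + [NON] * 18
        hi = roc_sweep(scores, labels, HIGH_IS_NEOPLASTIC).auc
        lo = roc_sweep(scores, labels, LOW_IS_NEOPLASTIC).auc
        assert hi + lo == pytest.approx(1.0)

    def test_strictly_increasing_transform_preserves_roc(self, rng):
        scores = rng.normal(size=25)
        labels = [NEO] * 10 + [NON] * 15
        base = roc_sweep(scores, labels)
        for transform in (lambda x: 2 * x + 1, np.exp):
            other = roc_sweep(transform(scores), labels)
            assert other.auc == pytest.approx(base.auc, abs=1e-12)
            assert np.array_equal(other.sensitivity, base.sensitivity)
            assert np.array_equal(other.specificity, base.specificity)

    @settings(derandomize=True, max_examples=50)
    @given(
        scores=st.lists(st.integers(-100, 100), min_size=2, max_size=20),
        shift=st.integers(-50, 50),
    )
    def test_constant_shift_preserves_auc(self, scores, shift):
        # integer scores keep the tie structure exact under the shift
        n = len(scores)
        labels = [NEO] * (n // 2 + 1) + [NON] * (n - n // 2 - 1)
        labels[-1] = NON
        base = roc_sweep([float(s) for s in scores], labels)
        shifted = roc_sweep([float(s + shift) for s in scores], labels)
        assert shifted.auc == pytest.approx(base.auc, abs=1e-12)

    def test_nan_score_names_the_site(self):
        with pytest.raises(ValidationError, match="siteB"):
            roc_sweep([0.1, math.nan], [NEO, NON], site_ids=["siteA", "siteB"])

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="both"):
            roc_sweep([0.1, 0.2], [NEO, NEO])


class TestQPoint:
    def test_perfect_curve_selects_perfect_point(self):
        curve = roc_sweep([0.9, 0.8, 0.4, 0.3], [NEO, NEO, NON, NON])
        op = q_point(curve)
        assert (op.sensitivity, op.specificity) == (1.0, 1.0)

    def test_diagonal_curve_selects_midpoint(self):
        # all scores tied: curve has only (1,0), (0,1); with a half split the
        # closest achievable point to (0,1) among enumerated points
        curve = roc_sweep([1, 1, 2, 2], [NON, NEO, NON, NEO])
        op = q_point(curve)
        assert op.sensitivity == pytest.approx(0.5)
        assert op.specificity == pytest.approx(0.5)

    def test_nearest_point_wins(self):
        curve = roc_sweep(
            [0.9, 0.85, 0.8, 0.5, 0.4, 0.3, 0.2],
            [NEO, NEO, NON, NEO, NON, NON, NON],
        )
        op = q_point(curve)
        # threshold 0.5: sens 3/3=1.0? enumerate: expect the point minimizing
        # squared distance; verify against brute force over the curve
        d2 = [
            (1 - p.specificity) ** 2 + (1 - p.sensitivity) ** 2 for p in curve.points()
        ]
        best = min(d2)
        op_d2 = (1 - op.specificity) ** 2 + (1 - op.sensitivity) ** 2
        assert op_d2 == pytest.approx(best)

    def test_ties_broken_by_higher_sensitivity_then_lower_threshold(self):
        curve = ROCCurve(
            thresholds=np.array([0.0, 1.0, 2.0]),
            sensitivity=np.array([0.6, 0.8, 0.8]),
            specificity=np.array([1.0, 0.8, 0.8]),
            auc=0.5,
            direction=HIGH_IS_NEOPLASTIC,
        )
        op = q_point(curve)
        assert op.sensitivity == 0.8 and op.threshold == 1.0

    def test_sens_eq_spec_rule(self):
        curve = roc_sweep(
            [0.9, 0.8, 0.7, 0.6, 0.5, 0.4], [NEO, NEO, NEO, NON, NON, NON]
        )
        op = q_point(curve, rule=SENS_EQ_SPEC)
        assert op.sensitivity == op.specificity == 1.0


class TestFitSingleFeature:
    def test_separable_feature_threshold_strictly_between_supports(self):
        values = [0.2, 0.3, 0.4, 0.7, 0.8, 0.9]
        labels = [NON, NON, NON, NEO, NEO, NEO]
        model, curve = fit_single_feature(values, labels)
        assert curve.auc == 1.0
        assert 0.4 < model.threshold < 0.7
        assert model.direction == HIGH_IS_NEOPLASTIC

    def test_constant_feature_warns_and_gives_auc_half(self):
        with pytest.warns(UserWarning, match="no discriminative"):
            model, curve = fit_single_feature([1.0] * 6, [NEO, NON] * 3)
        assert curve.auc == pytest.approx(0.5)

    def test_undefined_values_dropped_with_warning(self):
        values = [0.1, 0.2, math.nan, 0.8, 0.9]
        labels = [NON, NON, NON, NEO, NEO]
        with pytest.warns(UserWarning, match="dropped 1"):
            model, curve = fit_single_feature(values, labels)
        assert curve.auc == 1.0

    def test_model_reproduces_q_point_on_training_data(self, rng):
        values = rng.normal(size=60) + np.r_[np.full(25, 1.0), np.zeros(35)]
        labels = [NEO] * 25 + [NON] * 35
        model, curve = fit_single_feature(values, labels)
        pred = model.predict(values)
        pos = np.array([l == NEO for l in labels])
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        assert sens == pytest.approx(model.sensitivity)
        assert spec == pytest.approx(model.specificity)

    def test_lower_scores_for_neoplastic_flip_direction(self):
        values = [0.9, 0.8, 0.2, 0.1]
        labels = [NON, NON, NEO, NEO]
        model, curve = fit_single_feature(values, labels)
        assert model.direction == LOW_IS_NEOPLASTIC
        assert curve.auc == 1.0


class TestRankFeatures:
    def test_perfect_feature_ranks_above_constant(self):
        table = {
            "separating": [0.1, 0.2, 0.8, 0.9],
            "flat": [1.0, 1.0, 1.0, 1.0],
        }
        labels = [NON, NON, NEO, NEO]
        with pytest.warns(UserWarning):
            ranking = rank_features(table, labels)
        assert list(ranking["feature"]) == ["separating", "flat"]
        assert ranking["auc"].tolist() == pytest.approx([1.0, 0.5])

    def test_duplicate_feature_ties_broken_alphabetically(self):
        values = [0.1, 0.4, 0.6, 0.9]
        labels = [NON, NEO, NON, NEO]
        ranking = rank_features({"zeta": values, "alpha": values}, labels)
        assert list(ranking["feature"]) == ["alpha", "zeta"]
        assert ranking["auc"][0] == ranking["auc"][1]


class TestFitMultiFeature:
    def test_identical_features_match_single_feature_auc(self, rng):
        x = rng.normal(size=80) + np.r_[np.full(30, 0.8), np.zeros(50)]
        labels = [NEO] * 30 + [NON] * 50
        _, single = fit_single_feature(x, labels)
        _, multi = fit_multi_feature(np.column_stack([x, x]), labels)
        assert multi.auc == pytest.approx(single.auc, abs=1e-9)

    def test_pure_noise_second_feature_changes_little(self):
        rng = np.random.default_rng(17)
        n = 200
        labels = [NEO] * 80 + [NON] * 120
        x = rng.normal(size=n) + np.r_[np.full(80, 1.2), np.zeros(120)]
        noise = rng.normal(size=n)
        _, single = fit_single_feature(x, labels)
        _, multi = fit_multi_feature(np.column_stack([x, noise]), labels)
        assert abs(multi.auc - single.auc) < 0.05

    def test_jointly_separable_rotated_gaussians_beat_each_margin(self):
        rng = np.random.default_rng(17)
        n = 150
        # discriminative direction at 45 degrees; each margin overlaps heavily
        base = rng.normal(size=(2 * n, 2)) @ np.array([[1.0, 0.99], [0.99, 1.0]])
        shift = np.array([1.0, -1.0]) * 1.5
        X = np.vstack([base[:n] + shift, base[n:]])
        labels = [NEO] * n + [NON] * n
        _, f1 = fit_single_feature(X[:, 0], labels)
        _, f2 = fit_single_feature(X[:, 1], labels)
        _, multi = fit_multi_feature(X, labels)
        assert multi.auc > max(f1.auc, f2.auc) + 0.05

    def test_matches_sklearn_lda_projection(self):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3))
        X[:25] += np.array([0.8, -0.3, 0.5])
        labels = [NEO] * 25 + [NON] * 35
        _, multi = fit_multi_feature(X, labels)
        clf = sklearn_lda().fit(X, [1] * 25 + [0] * 35)
        scores = clf.decision_function(X)
        oracle = mann_whitney_auc(scores, labels)
        assert multi.auc == pytest.approx(oracle, abs=1e-9)

    def test_undefined_values_rejected(self):
        X = np.array([[0.1, 0.2], [math.nan, 0.3], [0.5, 0.6], [0.7, 0.8]])
        with pytest.raises(ValidationError, match="undefined"):
            fit_multi_feature(X, [NON, NON, NEO, NEO])
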