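"""Splits, metric panels, ROC/AUC and the three classification designs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evmir import (
    confusion_metrics,
    roc_auc,
    run_design_cross_cohort,
    run_design_forest,
    run_design_logistic,
    stratified_split,
)
from evmir.errors import AlignmentError, StratificationError, ValidationError


def _gaussian_cohort(rng, n_pos, n_neg, n_features=8, shift=2.0, informative=None):
    informative = informative if informative is not None else n_features
    shifts = np.zeros(n_features)
    shifts[:informative] = shift * np.linspace(1.0, 0.4, informative)
    pos = rng.normal(0, 1, size=(n_pos, n_features)) + shifts
    neg = rng.normal(0, 1, size=(n_neg, n_features))
    x = np.vstack([pos, neg])
    ids = [f"A{i}" for i in range(n_pos)] + [f"H{i}" for i in range(n_neg)]
    features = pd.DataFrame(x, index=ids, columns=[f"miR-{j}" for j in range(n_features)])
    labels = pd.Series(["ALS"] * n_pos + ["HC"] * n_neg, index=ids)
    return features, labels


class TestStratifiedSplit:
    def test_cohort_of_269_splits_216_53(self):
        """ceil(0.8 x 269) = 216 train, 53 test — the split whose logistic
        fit yields 215 null and 207 residual degrees of freedom."""
        ids = [f"S{i}" for i in range(269)]
        labels = ["ALS"] * 119 + ["HC"] * 150
        plan = stratified_split(ids, labels, 0.8, seed=375)
        assert len(plan.train_ids) == 216
        assert len(plan.test_ids) == 53
        assert not set(plan.train_ids) & set(plan.test_ids)
        assert set(plan.train_ids) | set(plan.test_ids) == set(ids)

    def test_balanced_small_split_preserves_stratification(self):
        ids = [f"S{i}" for i in range(10)]
        labels = ["ALS"] * 5 + ["HC"] * 5
        plan = stratified_split(ids, labels, 0.5, seed=1)
        train_labels = [labels[int(s[1:])] for s in plan.train_ids]
        assert len(plan.train_ids) == 5
        assert sorted(train_labels).count("ALS") in (2, 3)

    def test_same_seed_same_plan(self):
        ids = [f"S{i}" for i in range(40)]
        labels = ["ALS"] * 15 + ["HC"] * 25
        a = stratified_split(ids, labels, 0.8, seed=7)
        b = stratified_split(ids, labels, 0.8, seed=7)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_tiny_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_split(["a", "b", "c"], ["ALS", "HC", "HC"], 0.5, seed=1)


class TestConfusionMetrics:
    def test_perfect(self):
        m = confusion_metrics(2, 0, 2, 0)
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_forced_arithmetic(self):
        m = confusion_metrics(9, 2, 8, 1)
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["ppv"] == pytest.approx(100 * 9 / 11)
        assert m["npv"] == pytest.approx(100 * 8 / 9)
        assert m["accuracy"] == pytest.approx(85.0)

    def test_degenerate_ratios_not_applicable(self):
        m = confusion_metrics(0, 0, 5, 5)
        assert m["sensitivity"] == pytest.approx(0.0)
        assert m["ppv"] is None  # never silently 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            confusion_metrics(-1, 0, 1, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        auc, _ = roc_auc([0.5] * 6, [True, False] * 3)
        assert auc == pytest.approx(0.5)

    def test_matches_exhaustive_pair_counting(self):
        """4 positives / 4 negatives with an overlap and a tie: AUC equals
        the fraction of concordant pairs with ties counted half."""
        scores = [0.9, 0.8, 0.6, 0.4, 0.6, 0.3, 0.2, 0.1]
        labels = [True, True, True, True, False, False, False, False]
        auc, _ = roc_auc(scores, labels)
        pos = [s for s, l in zip(scores, labels) if l]
        neg = [s for s, l in zip(scores, labels) if not l]
        pairs = sum(
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        )
        assert auc == pytest.approx(pairs / (len(pos) * len(neg)))

    @given(
        shift=st.floats(min_value=0.1, max_value=3.0),
        scale=st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(max_examples=30, derandomize=True)
    def test_invariant_under_monotone_transforms(self, shift, scale):
        rng = np.random.default_rng(19)
        scores = rng.normal(0, 1, 30)
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        base, _ = roc_auc(scores, labels)
        linear, _ = roc_auc(scale * scores + shift, labels)
        expo, _ = roc_auc(np.exp(scores), labels)
        assert base == pytest.approx(linear) == pytest.approx(expo)


class TestLogisticDesign:
    def test_separated_clouds_classify_cleanly(self):
        rng = np.random.default_rng(101)
        features, labels = _gaussian_cohort(rng, 60, 70, shift=3.0)
        report = run_design_logistic(features, labels, seed=375)
        assert report.metrics["sensitivity"] > 95.0
        assert report.metrics["specificity"] > 95.0
        assert report.auc > 0.95

    def test_df_bookkeeping_at_n269(self):
        """Train 216 of 269 -> null df 215, residual df 207 with 8 features."""
        rng = np.random.default_rng(5)
        features, labels = _gaussian_cohort(rng, 119, 150, shift=1.0)
        report = run_design_logistic(features, labels, fraction=0.8, seed=375)
        assert report.n_train == 216
        assert report.deviance["df_null"] == 215
        assert report.deviance["df_residual"] == 207
        assert report.confusion["tp"] + report.confusion["fp"] + report.confusion[
            "tn"
        ] + report.confusion["fn"] == report.n_test == 53

    def test_coefficient_table_shape(self):
        rng = np.random.default_rng(5)
        features, labels = _gaussian_cohort(rng, 119, 150, shift=0.8)
        report = run_design_logistic(features, labels, seed=375)
        if not report.separation_flag:
            assert list(report.coefficients.columns) == ["estimate", "std_error", "z", "p"]
            assert len(report.coefficients) == 9  # intercept + 8 features

    def test_separation_is_flagged_and_coefficients_withheld(self):
        rng = np.random.default_rng(2)
        features, labels = _gaussian_cohort(rng, 30, 30, shift=12.0)
        report = run_design_logistic(features, labels, seed=375)
        assert report.separation_flag
        assert report.coefficients is None

    def test_permuted_labels_give_null_auc(self):
        """Median AUC over label permutations sits near one half."""
        rng = np.random.default_rng(3)
        features, labels = _gaussian_cohort(rng, 119, 150, shift=2.0)
        aucs = []
        for i in range(7):
            perm = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            rep = run_design_logistic(features, perm, seed=375)
            aucs.append(rep.auc)
        assert 0.35 <= float(np.median(aucs)) <= 0.65


class TestForestDesign:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(8)
        features, labels = _gaussian_cohort(rng, 60, 60, shift=1.5, informative=6)
        a = run_design_forest(features, labels, seed=375, n_trees=80)
        b = run_design_forest(features, labels, seed=375, n_trees=80)
        assert a.features == b.features
        assert a.metrics == b.metrics
        assert a.auc == pytest.approx(b.auc)

    def test_iterative_removal_drops_null_features(self):
        """With 6 informative and 2 pure-noise features, the selected subset
        usually excludes at least one noise feature, and noise importances
        stay below the strongest signal importances."""
        hits = 0
        excluded_noise = 0
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            features, labels = _gaussian_cohort(
                rng, 60, 60, shift=1.5, informative=6
            )
            rep = run_design_forest(features, labels, seed=375, n_trees=100)
            noise = {"miR-6", "miR-7"}
            if noise - set(rep.features):
                excluded_noise += 1
            full = run_design_forest(
                features, labels, seed=375, n_trees=100, iterative_removal=False
            )
            imp = full.importances
            if imp[["miR-6", "miR-7"]].max() < imp[["miR-0", "miR-1"]].max():
                hits += 1
        assert excluded_noise >= 6
        assert hits >= 6

    def test_metric_panel_consistent_with_confusion(self):
        rng = np.random.default_rng(12)
        features, labels = _gaussian_cohort(rng, 50, 50, shift=1.0)
        rep = run_design_forest(features, labels, seed=375, n_trees=60)
        c = rep.confusion
        total = sum(c.values())
        assert total == rep.n_test
        assert rep.metrics["accuracy"] == pytest.approx(
            100.0 * (c["tp"] + c["tn"]) / total
        )


class TestCrossCohortDesign:
    def test_independent_cohorts_comparable_to_random_split(self):
        rng = np.random.default_rng(42)
        train_x, train_y = _gaussian_cohort(rng, 50, 50, shift=2.0)
        test_x, test_y = _gaussian_cohort(rng, 119, 150, shift=2.0)
        test_x.index = [f"T{i}" for i in range(len(test_x))]
        test_y.index = test_x.index
        rep = run_design_cross_cohort(train_x, train_y, test_x, test_y, seed=101, n_trees=100)
        assert rep.metrics["accuracy"] > 85.0
        assert rep.n_test == 269

    def test_disjoint_features_rejected(self):
        rng = np.random.default_rng(1)
        a_x, a_y = _gaussian_cohort(rng, 10, 10, n_features=3)
        b_x, b_y = _gaussian_cohort(rng, 10, 10, n_features=3)
        b_x.columns = ["other-1", "other-2", "other-3"]
        with pytest.raises(AlignmentError):
            run_design_cross_cohort(a_x, a_y, b_x, b_y, seed=101, n_trees=20)

    def test_global_batch_shift_invisible_after_dcq(self):
        """A +1-cycle shift on every target including the references cancels
        in the dCq features, leaving the cross-cohort report unchanged."""
        import evmir

        rng = np.random.default_rng(33)
        cq = 30.0 + rng.normal(0, 1.0, size=(20, 5))
        samples = [f"S{i}" for i in range(20)]
        targets = ["t1", "t2", "r1", "r2", "r3"]
        m1 = evmir.CqMatrix(
            values=pd.DataFrame(cq, index=samples, columns=targets),
            plate_of={s: "P1" for s in samples},
        )
        m2 = evmir.CqMatrix(
            values=m1.values + 1.0, plate_of=dict(m1.plate_of)
        )
        d1 = evmir.normalize_dcq(m1, refs=["r1", "r2", "r3"], targets=["t1", "t2"]).values
        d2 = evmir.normalize_dcq(m2, refs=["r1", "r2", "r3"], targets=["t1", "t2"]).values
        pd.testing.assert_frame_equal(d1, d2)
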