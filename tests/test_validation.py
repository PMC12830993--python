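"""Fold planning, CV accounting, permutation null, SMOTE and ROC."""

import numpy as np
import pandas as pd
import pytest

import pirlms
from pirlms.validation import (
    CvReport,
    _smote_oversample,
    cross_validate,
    duty_cycle,
    make_folds,
    make_smote_oversampler,
    permute_labels,
    roc_curve,
    sensitivity,
    smote_cross_validate,
    specificity,
)


def _specimen_table(n_lymphoma, n_pdx, events_each=3):
    rows = []
    for cls, n in (("lymphoma", n_lymphoma), ("pdx", n_pdx)):
        for i in range(n):
            for e in range(events_each):
                rows.append(
                    {
                        "event_id": f"{cls}{i}e{e}",
                        "specimen_id": f"{cls}{i}",
                        "class_label": cls,
                    }
                )
    return pd.DataFrame(rows)


class TestMakeFolds:
    def test_study_shaped_plan_balances_folds(self):
        ann = _specimen_table(20, 90)
        plan = make_folds(ann, k=5, seed=0)
        per_fold = pd.Series(plan.assignment).value_counts()
        assert sorted(per_fold) == [22, 22, 22, 22, 22]
        # each fold holds ~4 lymphoma specimens
        for fold in range(5):
            lymph = sum(
                1 for s in plan.test_specimens(fold) if s.startswith("lymphoma")
            )
            assert 3 <= lymph <= 5

    def test_no_leakage_any_fold(self):
        ann = _specimen_table(5, 9)
        plan = make_folds(ann, k=3, seed=1)
        for fold in range(3):
            test = plan.test_specimens(fold)
            train = set(plan.assignment) - test
            assert not (test & train)

    def test_leave_one_specimen_out_limit(self):
        ann = _specimen_table(3, 3, events_each=2)
        plan = make_folds(ann, k=6, seed=0)
        assert all(len(plan.test_specimens(f)) == 1 for f in range(6))

    def test_too_few_specimens_rejected(self):
        with pytest.raises(ValueError, match="specimens"):
            make_folds(_specimen_table(1, 2), k=5)

    def test_seed_reproducible(self):
        ann = _specimen_table(6, 10)
        assert make_folds(ann, 4, seed=9) == make_folds(ann, 4, seed=9)


class TestCvReportAccounting:
    def test_conservation_enforced(self):
        with pytest.raises(ValueError, match="conserve"):
            CvReport.from_counts(total=10, correct=5, misclassified=1, unclassifiable=1)

    def test_two_denominator_accuracies(self):
        rep = CvReport.from_counts(100, 80, 10, 10)
        assert rep.accuracy_per_classifiable == pytest.approx(100 * 80 / 90)
        assert rep.accuracy_per_all == pytest.approx(80.0)
        assert rep.duty_cycle == pytest.approx(90.0)


class TestCrossValidate:
    def test_separable_cohort_perfect_per_classifiable(self, small_cohort):
        _, _, _, matrix = small_cohort
        ann = matrix.annotations
        plan = make_folds(ann[matrix.good_mask()], k=3, seed=0)
        rep = cross_validate(matrix, ann["class_label"].to_numpy(), plan)
        assert rep.misclassified == 0
        assert rep.accuracy_per_classifiable == 100.0
        # conservation per fold and in total
        f = rep.folds
        assert (f["correct"] + f["misclassified"] + f["unclassifiable"] == f["total"]).all()

    def test_confusion_margins_match_class_totals(self, small_cohort):
        _, _, _, matrix = small_cohort
        ann = matrix.annotations
        good = matrix.good_mask() & ~ann["empty_row"].to_numpy()
        plan = make_folds(ann[matrix.good_mask()], k=3, seed=0)
        rep = cross_validate(matrix, ann["class_label"].to_numpy(), plan)
        totals = ann.loc[good, "class_label"].value_counts()
        for cls in rep.confusion.index:
            assert rep.confusion.loc[cls].sum() == totals[cls]

    def test_duplicated_specimen_cannot_inflate_accuracy(self, small_cohort):
        """Grouping shields accuracy from within-specimen duplication: the
        duplicate travels with its specimen, so per-classifiable accuracy is
        unchanged though counts double for that specimen."""
        _, _, _, matrix = small_cohort
        ann = matrix.annotations
        plan = make_folds(ann[matrix.good_mask()], k=3, seed=0)
        rep = cross_validate(matrix, ann["class_label"].to_numpy(), plan)

        dup_spec = ann["specimen_id"].iloc[0]
        m = (ann["specimen_id"] == dup_spec).to_numpy()
        values = np.vstack([matrix.values, matrix.values[m]])
        ann2 = pd.concat([ann, ann[m]], ignore_index=True)
        ann2.loc[len(ann):, "event_id"] += "-dup"
        matrix2 = pirlms.BinnedMatrix(values, matrix.bin_edges, ann2)
        rep2 = cross_validate(matrix2, ann2["class_label"].to_numpy(), plan)
        good = matrix.good_mask() & ~ann["empty_row"].to_numpy()
        assert rep2.total == rep.total + (m & good).sum()
        assert rep2.accuracy_per_classifiable == rep.accuracy_per_classifiable


class TestPermuteLabels:
    def test_balanced_pseudo_groups(self):
        ann = _specimen_table(20, 90)
        labels, table = permute_labels(ann, seed=0)
        counts = table["pseudo_group"].value_counts()
        assert sorted(counts) == [55, 55]
        # both pseudo-groups mix both true classes
        merged = table.merge(
            ann[["specimen_id", "class_label"]].drop_duplicates(), on="specimen_id"
        )
        mix = merged.groupby("pseudo_group")["class_label"].nunique()
        assert (mix == 2).all()

    def test_event_count_conserved(self):
        ann = _specimen_table(10, 12, events_each=4)
        labels, _ = permute_labels(ann, seed=3)
        assert len(labels) == len(ann)
        assert labels.notna().all()

    def test_specimens_move_whole(self):
        ann = _specimen_table(6, 6)
        labels, _ = permute_labels(ann, seed=1)
        per_spec = pd.DataFrame(
            {"specimen_id": ann["specimen_id"], "g": labels}
        ).groupby("specimen_id")["g"].nunique()
        assert (per_spec == 1).all()

    def test_seed_reproducible(self):
        ann = _specimen_table(8, 8)
        l1, t1 = permute_labels(ann, seed=5)
        l2, t2 = permute_labels(ann, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_too_few_specimens_rejected(self):
        with pytest.raises(ValueError):
            permute_labels(_specimen_table(1, 2))


class TestSmote:
    def test_minority_balanced_to_majority(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(5, 1, (10, 3))])
        y = np.array(["maj"] * 40 + ["min"] * 10)
        Xs, ys = _smote_oversample(X, y, rng)
        assert (ys == "min").sum() == 40
        assert (ys == "maj").sum() == 40
        # synthetic points interpolate the minority cloud
        synth = Xs[50:]
        assert synth.min() > X[y == "min"].min() - 1e-9
        assert synth.max() < X[y == "min"].max() + 1e-9

    def test_neighbour_count_reduced_with_warning(self):
        rng = np.random.default_rng(0)
        X = np.vstack([np.random.default_rng(1).normal(0, 1, (10, 2)), [[5, 5], [6, 6], [5, 6]]])
        y = np.array(["maj"] * 10 + ["min"] * 3)
        with pytest.warns(UserWarning, match="reduced"):
            _smote_oversample(X, y, rng, k_neighbors=5)

    def test_test_folds_identical_to_plain_cv(self, small_cohort):
        _, _, _, matrix = small_cohort
        ann = matrix.annotations
        plan = make_folds(ann[matrix.good_mask()], k=3, seed=0)
        y = ann["class_label"].to_numpy()
        plain = cross_validate(matrix, y, plan)
        smoted = smote_cross_validate(matrix, y, plan, seed=0)
        pd.testing.assert_frame_equal(
            plain.event_results[["event_id", "fold", "true"]],
            smoted.event_results[["event_id", "fold", "true"]],
        )
        assert (plain.folds["total"] == smoted.folds["total"]).all()

    def test_balanced_input_near_noop(self):
        """With balanced classes SMOTE adds nothing, so the fitted model and
        the report match plain CV exactly."""
        cfg = pirlms.CohortConfig(
            n_specimens_per_class=(6, 6), events_per_specimen=4, seed=21
        )
        scans, truth = pirlms.generate_cohort(cfg)
        matrix = pirlms.run_pipeline(scans, truth)
        ann = matrix.annotations
        plan = make_folds(ann[matrix.good_mask()], k=3, seed=0)
        y = ann["class_label"].to_numpy()
        plain = cross_validate(matrix, y, plan)
        smoted = smote_cross_validate(matrix, y, plan, seed=0)
        # specimen counts are balanced; event counts may differ by a few
        # bad events, so SMOTE may add a handful of points at most
        assert abs(
            plain.accuracy_per_classifiable - smoted.accuracy_per_classifiable
        ) < 1.0


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array(["lymphoma", "lymphoma", "pdx", "pdx"])
        _, auc = roc_curve(scores, labels)
        assert auc == 1.0

    def test_four_point_enumeration(self):
        # scores (0.1, 0.4, 0.6, 0.9), labels (0, 0, 1, 1): every positive
        # outranks every negative, so AUC = 1
        _, auc = roc_curve(
            np.array([0.1, 0.4, 0.6, 0.9]), np.array([0, 0, 1, 1]), positive_class=1
        )
        assert auc == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(12)
        scores = rng.random(4000)
        labels = rng.choice(["lymphoma", "pdx"], size=4000)
        _, auc = roc_curve(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.1, 0.9]), np.array(["pdx", "pdx"]))


def test_accounting_primitives_match_standard_definitions():
    assert sensitivity(9, 1) == pytest.approx(90.0)
    assert specificity(99, 1) == pytest.approx(99.0)
    assert duty_cycle(93, 100) == pytest.approx(93.0)
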