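import math

import numpy as np
import pandas as pd
import pytest

from msdeeg import evaluation as ev
from msdeeg.features import FeatureMatrix


def make_fm(X, y=None, subjects=None, states=None, groups=None):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if states is None:
        states = np.where((y if y is not None else np.zeros(n)) == 1,
                          "task", "rest")
    if groups is None:
        groups = ["low_stress"] * n
    labels = pd.DataFrame({
        "subject_id": subjects if subjects is not None else ["S01"] * n,
        "state": states,
        "group": groups,
    })
    data = pd.DataFrame(X, columns=[f"Fp1__f{i}" for i in range(X.shape[1])])
    return FeatureMatrix(data=data, labels=labels, feature_set="set3")


class TestFolds:
    def test_kfold5_partitions_all_trials(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=100)
        fm = make_fm(rng.normal(size=(100, 3)), y=y)
        plan = ev.make_folds(fm, "kfold5", seed=1)
        assert plan.n_folds == 5
        sizes = np.bincount(plan.assignments)
        assert (plan.assignments >= 0).all()
        assert sizes.sum() == 100 and sizes.min() >= 19 and sizes.max() <= 21

    def test_loso_one_fold_per_subject_and_disjoint(self):
        rng = np.random.default_rng(1)
        subjects = np.repeat([f"S{i:02d}" for i in range(36)], 4)
        fm = make_fm(rng.normal(size=(144, 2)),
                     y=rng.integers(0, 2, size=144), subjects=subjects)
        plan = ev.make_folds(fm, "leave_subject_out", seed=0)
        assert plan.n_folds == 36
        for f in range(plan.n_folds):
            test_subj = set(fm.labels["subject_id"][plan.assignments == f])
            train_subj = set(fm.labels["subject_id"][plan.assignments != f])
            assert len(test_subj) == 1
            assert not test_subj & train_subj

    def test_loso_single_subject_rejected(self):
        fm = make_fm(np.zeros((10, 2)), y=np.zeros(10))
        with pytest.raises(ValueError):
            ev.make_folds(fm, "leave_subject_out")


class TestMetrics:
    def test_hand_computed_example(self):
        m = ev.compute_metrics(ev.ConfusionCounts(TP=90, TN=80, FP=20, FN=10))
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.8182, abs=1e-4)
        assert m["goodness_index"] == pytest.approx(0.2236, abs=1e-4)
        assert m["mcc"] == pytest.approx(0.7035, abs=1e-4)
        assert m["dor"] == pytest.approx(36.0)

    def test_perfect_classifier(self):
        m = ev.compute_metrics(ev.ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0
        assert m["precision"] == 1.0 and m["mcc"] == 1.0
        assert m["goodness_index"] == 0.0
        assert math.isinf(m["dor"]) and m["dor_infinite"]

    def test_no_information_point(self):
        m = ev.compute_metrics(ev.ConfusionCounts(TP=25, TN=25, FP=25, FN=25))
        assert m["accuracy"] == 0.5 and m["mcc"] == 0.0 and m["dor"] == 1.0

    def test_single_zero_cell_gets_continuity_correction(self):
        m = ev.compute_metrics(ev.ConfusionCounts(TP=10, TN=10, FP=0, FN=5))
        assert m["dor_corrected"] and not m["dor_infinite"]
        assert m["dor"] == pytest.approx((10.5 * 10.5) / (0.5 * 5.5))

    def test_dor_sensitivity_specificity_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(1, 200, size=4)
            m = ev.compute_metrics(ev.ConfusionCounts(int(tp), int(tn),
                                                      int(fp), int(fn)))
            se, sp = m["sensitivity"], m["specificity"]
            assert m["dor"] == pytest.approx(
                (se / (1 - se)) / ((1 - sp) / sp), rel=1e-9)

    def test_mcc_range_and_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 100, size=4))
            m = ev.compute_metrics(ev.ConfusionCounts(tp, tn, fp, fn))
            swapped = ev.compute_metrics(ev.ConfusionCounts(tn, tp, fn, fp))
            assert -1.0 <= m["mcc"] <= 1.0
            assert swapped["mcc"] == pytest.approx(m["mcc"])  # symmetric swap
            assert swapped["sensitivity"] == pytest.approx(m["specificity"])
            assert swapped["specificity"] == pytest.approx(m["sensitivity"])

    def test_mcc_sign_flips_when_predictions_inverted(self):
        m = ev.compute_metrics(ev.ConfusionCounts(TP=90, TN=80, FP=20, FN=10))
        inv = ev.compute_metrics(ev.ConfusionCounts(TP=10, TN=20, FP=80, FN=90))
        assert inv["mcc"] == pytest.approx(-m["mcc"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ev.compute_metrics(ev.ConfusionCounts())


class TestSummary:
    def test_identical_folds_zero_width_ci(self):
        counts = [ev.ConfusionCounts(TP=8, TN=8, FP=2, FN=2)] * 5
        rep = ev.summarize_with_ci(counts)
        mean, lo, hi = rep.point["accuracy"]
        assert mean == lo == hi == pytest.approx(0.8)

    def test_two_fold_mean_is_symmetric(self):
        counts = [ev.ConfusionCounts(TP=40, TN=40, FP=10, FN=10),
                  ev.ConfusionCounts(TP=45, TN=45, FP=5, FN=5)]
        rep = ev.summarize_with_ci(counts)
        mean, lo, hi = rep.point["accuracy"]
        assert mean == pytest.approx(0.85)
        assert mean - lo == pytest.approx(hi - mean)

    def test_bootstrap_close_to_t_for_near_normal_folds(self):
        rng = np.random.default_rng(9)
        counts = []
        for _ in range(12):
            acc = np.clip(rng.normal(0.8, 0.02), 0, 1)
            tp = int(round(acc * 100))
            counts.append(ev.ConfusionCounts(TP=tp, TN=tp, FP=100 - tp,
                                             FN=100 - tp))
        rep_t = ev.summarize_with_ci(counts, ci_method="t")
        rep_b = ev.summarize_with_ci(counts, ci_method="bootstrap", seed=1)
        for a, b in zip(rep_t.point["accuracy"], rep_b.point["accuracy"]):
            assert abs(a - b) < 0.01

    def test_pooled_counts_are_summed(self):
        counts = [ev.ConfusionCounts(TP=10, TN=10, FP=0, FN=0),
                  ev.ConfusionCounts(TP=9, TN=9, FP=1, FN=1)]
        rep = ev.summarize_with_ci(counts)
        assert rep.pooled["accuracy"] == pytest.approx(38 / 40)

    def test_needs_two_folds(self):
        with pytest.raises(ValueError):
            ev.summarize_with_ci([ev.ConfusionCounts(TP=1, TN=1, FP=1, FN=1)])


class TestReliabilityGate:
    def test_strong_system_passes(self):
        counts = [ev.ConfusionCounts(TP=99, TN=99, FP=1, FN=1)] * 2
        gate = ev.reliability_gate(ev.summarize_with_ci(counts))
        assert gate["overall"]

    def test_low_sensitivity_fails_naming_it(self):
        # Se = 0.79, Sp/precision high
        counts = [ev.ConfusionCounts(TP=79, TN=999, FP=1, FN=21)] * 2
        gate = ev.reliability_gate(ev.summarize_with_ci(counts))
        assert not gate["sensitivity"] and not gate["overall"]
        assert gate["specificity"] and gate["precision"]

    def test_infinite_dor_passes_that_criterion(self):
        counts = [ev.ConfusionCounts(TP=90, TN=90, FP=0, FN=0)] * 2
        gate = ev.reliability_gate(ev.summarize_with_ci(counts))
        assert gate["dor"] and gate["overall"]


class TestTrainAndPredict:
    def test_separated_clusters_are_perfect_with_1nn(self, knn_spec):
        rng = np.random.default_rng(5)
        X0 = rng.normal(0, 0.1, size=(60, 4))
        X1 = rng.normal(5, 0.1, size=(60, 4))
        y = np.array([0] * 60 + [1] * 60)
        fm = make_fm(np.vstack([X0, X1]), y=y)
        plan = ev.make_folds(fm, "kfold5", seed=2)
        counts = ev.train_and_predict(fm, plan, knn_spec)
        for c in counts:
            assert c.FP == 0 and c.FN == 0

    def test_permuted_labels_give_chance_accuracy(self, knn_spec):
        rng = np.random.default_rng(6)
        n = 600
        X = rng.normal(size=(n, 6))
        y = rng.permutation(np.repeat([0, 1], n // 2))
        fm = make_fm(X, y=y)
        plan = ev.make_folds(fm, "kfold5", seed=3)
        pooled = sum(ev.train_and_predict(fm, plan, knn_spec),
                     ev.ConfusionCounts())
        acc = ev.compute_metrics(pooled)["accuracy"]
        assert 0.40 <= acc <= 0.60

    def test_same_seed_reproduces_counts(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 5))
        y = rng.integers(0, 2, size=120)
        fm = make_fm(X, y=y)
        spec = ev.ClassifierSpec(kind="random_forest", seed=11)
        a = ev.train_and_predict(fm, ev.make_folds(fm, "kfold5", seed=4), spec)
        b = ev.train_and_predict(fm, ev.make_folds(fm, "kfold5", seed=4), spec)
        assert [vars(c) for c in a] == [vars(c) for c in b]

    def test_single_class_training_fold_skipped_with_warning(self, knn_spec):
        X = np.random.default_rng(8).normal(size=(10, 2))
        y = np.array([0] * 5 + [1] * 4 + [0])  # subject B is all one class
        subjects = ["A"] * 9 + ["B"]
        fm = make_fm(X, y=y, subjects=subjects)
        plan = ev.make_folds(fm, "leave_subject_out")
        with pytest.warns(UserWarning, match="single-class"):
            counts = ev.train_and_predict(fm, plan, knn_spec)
        assert len(counts) == 1  # only subject B's fold has two-class training

    @pytest.mark.parametrize("kind", ev.CLASSIFIER_KINDS)
    def test_every_classifier_kind_runs(self, kind):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(4, 1, (40, 3))])
        y = np.array([0] * 40 + [1] * 40)
        fm = make_fm(X, y=y)
        rep = ev.run_validation(fm, ev.ClassifierSpec(kind=kind, seed=0), seed=5)
        assert rep.pooled["accuracy"] > 0.9

    def test_levels_task_uses_task_state_trials_only(self, knn_spec):
        rng = np.random.default_rng(10)
        n = 80
        states = ["rest", "task"] * (n // 2)
        groups = ["low_stress"] * (n // 2) + ["high_stress"] * (n // 2)
        fm = make_fm(rng.normal(size=(n, 3)), states=states, groups=groups,
                     subjects=[f"S{i % 8}" for i in range(n)])
        sub = ev.select_task_trials(fm, "levels")
        assert (sub.labels["state"] == "task").all()
        assert sub.n_trials == n // 2
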