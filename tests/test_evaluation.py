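import numpy as np
import pytest
from dataclasses import replace

from semgfatigue.classification import BaselineSpec
from semgfatigue.errors import LeakageError, ValidationError
from semgfatigue.evaluation import (
    ConfusionMatrix,
    PipelineConfig,
    compare_full_vs_consensus,
    confusion,
    metrics,
    roc_pr,
    run_loso,
)
from semgfatigue.synth import SubjectProfile, simulate_cohort


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = confusion(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        assert np.array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_toy_counts(self):
        cm = confusion([0, 0, 1, 1], [0, 1, 1, 1], [0, 1])
        assert np.array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_matches_bruteforce_tally(self, rng):
        true = rng.integers(0, 3, 1000)
        pred = rng.integers(0, 3, 1000)
        cm = confusion(true, pred, [0, 1, 2])
        brute = np.zeros((3, 3), dtype=int)
        for t, p in zip(true, pred):
            brute[t, p] += 1
        assert np.array_equal(cm.counts, brute)
        assert cm.total == 1000

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion([0, 5], [0, 0], [0, 1])


class TestMetrics:
    def test_diagonal_all_ones(self):
        cm = ConfusionMatrix(np.diag([10, 20, 5]), ("a", "b", "c"))
        m = metrics(cm)
        assert m["accuracy"] == 1.0
        assert m["precision"] == 1.0
        assert m["recall"] == 1.0
        assert m["f1"] == 1.0

    def test_hand_computed_two_class(self):
        cm = ConfusionMatrix(np.array([[45, 5], [10, 40]]), ("neg", "pos"))
        m = metrics(cm)
        assert m["accuracy"] == pytest.approx(0.85)
        pc = m["per_class"]["neg"]
        assert pc["precision"] == pytest.approx(45 / 55)
        assert pc["recall"] == pytest.approx(0.9)
        assert pc["f1"] == pytest.approx(2 * 45 / (90 + 5 + 10))

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 50, (3, 3))
            counts[np.diag_indices(3)] += 1  # avoid empty classes
            cm = ConfusionMatrix(counts, ("a", "b", "c"))
            m = metrics(cm)
            for pc in m["per_class"].values():
                pr, re = pc["precision"], pc["recall"]
                if pr + re > 0:
                    assert pc["f1"] == pytest.approx(2 * pr * re / (pr + re))

    def test_ovr_accuracy_equals_trace_for_two_classes(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 100, (2, 2))
            counts[0, 0] += 1
            cm = ConfusionMatrix(counts, ("a", "b"))
            m = metrics(cm)
            assert m["accuracy_ovr"] == pytest.approx(m["accuracy"])

    def test_macro_f1_between_min_and_max(self, rng):
        counts = rng.integers(1, 50, (3, 3))
        cm = ConfusionMatrix(counts, ("a", "b", "c"))
        m = metrics(cm)
        f1s = [v["f1"] for v in m["per_class"].values()]
        assert min(f1s) - 1e-12 <= m["f1"] <= max(f1s) + 1e-12

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionMatrix(np.zeros((2, 2), dtype=int), ("a", "b")))


class TestRocPr:
    def test_perfect_separation_auc_one(self):
        scores = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
        truth = np.array([1, 1, 0, 0])
        out = roc_pr(scores, truth, ("neg", "pos"))
        assert out["pos"]["roc_auc"] == pytest.approx(1.0)
        assert out["pos"]["pr_auc"] == pytest.approx(1.0)

    def test_null_scores_auc_half(self, rng):
        n = 10_000
        truth = rng.integers(0, 2, n)
        p = rng.uniform(0, 1, n)
        scores = np.column_stack([1 - p, p])
        out = roc_pr(scores, truth, ("neg", "pos"))
        assert abs(out["pos"]["roc_auc"] - 0.5) < 0.02

    def test_roc_curve_monotone(self, rng):
        n = 500
        truth = rng.integers(0, 2, n)
        p = np.clip(truth * 0.3 + rng.uniform(0, 0.7, n), 0, 1)
        scores = np.column_stack([1 - p, p])
        out = roc_pr(scores, truth, ("neg", "pos"))
        assert np.all(np.diff(out["pos"]["fpr"]) >= 0)
        assert np.all(np.diff(out["pos"]["tpr"]) >= 0)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        n = 400
        truth = rng.integers(0, 2, n)
        p = np.clip(truth * 0.4 + rng.uniform(0, 0.6, n), 0, 1)
        scores = np.column_stack([1 - p, p])
        out = roc_pr(scores, truth, ("neg", "pos"))
        assert out["pos"]["roc_auc"] == pytest.approx(roc_auc_score(truth, p), abs=1e-9)
        assert out["pos"]["pr_auc"] == pytest.approx(
            average_precision_score(truth, p), abs=1e-9
        )

    def test_single_class_truth_rejected(self):
        scores = np.array([[0.4, 0.6], [0.3, 0.7]])
        with pytest.raises(ValidationError):
            roc_pr(scores, np.array([1, 1]), ("neg", "pos"))


@pytest.fixture(scope="module")
def small_cohort():
    base = SubjectProfile(
        duration_s=15.0, rep_period_s=1.0, baseline_rms=0.15,
        rms_gain_end=2.0, mnf_start=120.0, mnf_end=70.0,
    )
    return simulate_cohort(5, base, seed=21)


@pytest.fixture(scope="module")
def rf_report(small_cohort):
    config = PipelineConfig(task="binary", representation="features")
    spec = BaselineSpec.published("random_forest", "binary")
    return run_loso(small_cohort, config, spec)


class TestRunLoso:
    def test_five_subjects_five_folds(self, rf_report):
        assert len(rf_report.folds) == 5

    def test_mean_accuracy_is_fold_mean(self, rf_report):
        accs = [f["metrics"]["accuracy"] for f in rf_report.folds]
        assert rf_report.aggregate["accuracy"]["mean"] == pytest.approx(np.mean(accs))
        assert rf_report.aggregate["accuracy"]["std"] == pytest.approx(np.std(accs))

    def test_beats_majority_class(self, rf_report):
        cm = rf_report.confusion_total.counts
        majority = cm.sum(axis=1).max() / cm.sum()
        assert rf_report.aggregate["accuracy"]["mean"] > majority

    def test_confusion_conservation(self, rf_report):
        for fold in rf_report.folds:
            assert int(np.sum(fold["confusion"])) == fold["n_test"]

    def test_report_serialises(self, rf_report, tmp_path):
        path = tmp_path / "run.json"
        rf_report.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["class_names"] == ["NoFatigue", "Fatigue"]
        assert len(payload["folds"]) == 5

    def test_corrupted_split_trips_hard_error(self, small_cohort, monkeypatch):
        import semgfatigue.evaluation as ev

        real = ev.loso_split

        def corrupt(ids):
            split = real(ids)
            train, test = split.folds[0]
            split.folds[0] = (tuple(ids), test)  # test subject leaked into train
            return split

        monkeypatch.setattr(ev, "loso_split", corrupt)
        config = PipelineConfig(task="binary", representation="features")
        spec = BaselineSpec.published("random_forest", "binary")
        with pytest.raises(LeakageError):
            run_loso(small_cohort, config, spec)

    def test_too_small_cohort_rejected(self, small_cohort):
        config = PipelineConfig(task="binary")
        spec = BaselineSpec.published("random_forest", "binary")
        with pytest.raises(ValidationError):
            run_loso(small_cohort[:1], config, spec)


class TestConsensusCompare:
    def test_consensus_evaluates_fewer_or_equal_windows(self, small_cohort):
        config = PipelineConfig(task="threeclass", representation="features")
        spec = BaselineSpec.published("random_forest", "threeclass")
        full, cons = compare_full_vs_consensus(small_cohort, config, spec)
        assert cons.extras["n_windows"] <= full.extras["n_windows"]
        assert [f["test_subject"] for f in full.folds] == [
            f["test_subject"] for f in cons.folds
        ]

    def test_zero_disagreement_reports_identical(self):
        # borg reports hand-aligned with the progress thirds: no upgrades
        base = SubjectProfile(duration_s=15.0, rep_period_s=1.0, baseline_rms=0.15,
                              rms_gain_end=2.0, mnf_start=120.0, mnf_end=70.0)
        cohort = simulate_cohort(3, base, seed=4)
        for rec in cohort:
            third = rec.duration_s / 3.0
            rec.borg_reports = [(0.0, 0), (third + 0.01, 3), (2 * third + 0.01, 6)]
        config = PipelineConfig(task="threeclass", representation="features")
        spec = BaselineSpec.published("random_forest", "threeclass")
        full, cons = compare_full_vs_consensus(cohort, config, spec)
        assert full.extras["n_windows"] == cons.extras["n_windows"]
        assert np.array_equal(full.confusion_total.counts, cons.confusion_total.counts)
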