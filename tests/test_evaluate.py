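"""Cross-validation protocol, metric formulas and scenario runners."""

import math

import numpy as np
import pytest

from mbhis import (
    AugmentationPolicy,
    ClassifierSpec,
    ConfigurationError,
    ConfusionCounts,
    CVConfig,
    DataError,
    ScenarioConfig,
    TrainConfig,
    compute_metrics,
    macro_metrics,
    run_scenario,
    split_folds,
)
from mbhis.evaluate import _audit_disjoint, confusion_matrix


class TestSplitFolds:
    def test_partition_covers_and_is_disjoint(self):
        y = np.repeat(np.arange(2), 50)
        cfg = CVConfig(k=5, repeats=5, base_seed=0)
        pairs = split_folds(y, cfg)
        assert len(pairs) == 25
        for r in range(5):
            tests = [set(pairs[5 * r + f][1]) for f in range(5)]
            assert all(len(t) == 20 for t in tests)
            assert set().union(*tests) == set(range(100))
            for i in range(5):
                for j in range(i + 1, 5):
                    assert not tests[i] & tests[j]

    def test_stratification_within_one_sample(self):
        y = np.repeat(np.arange(5), 10)
        for train_idx, test_idx in split_folds(y, CVConfig(k=5, repeats=2, base_seed=3)):
            counts = np.bincount(y[test_idx], minlength=5)
            assert np.all(np.abs(counts - 2) <= 1)

    def test_repeats_are_reproducible_and_distinct(self):
        y = np.repeat(np.arange(2), 20)
        a = split_folds(y, CVConfig(k=4, repeats=2, base_seed=9))
        b = split_folds(y, CVConfig(k=4, repeats=2, base_seed=9))
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)
        assert any(
            not np.array_equal(a[i][1], a[4 + i][1]) for i in range(4)
        )  # different repeats shuffle differently

    def test_small_class_is_named_in_error(self):
        y = np.array([0] * 10 + [1] * 3)
        with pytest.raises(ConfigurationError, match="class 1"):
            split_folds(y, CVConfig(k=5, repeats=1))


class TestMetrics:
    def test_hand_computed_counts(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert math.isclose(m["accuracy"], 0.7)
        assert math.isclose(m["sensitivity"], 0.6)
        assert math.isclose(m["specificity"], 0.8)
        assert math.isclose(m["precision"], 0.75)

    def test_perfect_binary_classifier_scores_ones(self):
        m = compute_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity", "specificity", "precision"))

    def test_zero_denominator_reports_nan_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert math.isnan(m["precision"])
        assert m["specificity"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_macro_metrics_from_confusion_matrix(self):
        cm = confusion_matrix([0, 0, 1, 1, 2, 2], [0, 1, 1, 1, 2, 0], 3)
        m = macro_metrics(cm)
        assert math.isclose(m["accuracy"], 4 / 6)
        # per-class sensitivities: 1/2, 2/2, 1/2 -> macro 2/3
        assert math.isclose(m["sensitivity"], (0.5 + 1.0 + 0.5) / 3)


class TestLeakageAudit:
    def test_disjoint_passes_overlap_raises(self):
        _audit_disjoint(["a", "b"], {"c", "d"})
        with pytest.raises(DataError, match="leakage"):
            _audit_disjoint(["a", "c"], {"c"})

    def test_augmented_copy_of_test_sample_raises(self):
        with pytest.raises(DataError, match="leakage"):
            _audit_disjoint(["x#aug0"], {"x"})


@pytest.fixture(scope="module")
def quick_cv():
    return CVConfig(k=5, repeats=2, base_seed=0)


class TestScenarios:
    def test_scenario_ii_entry_count_and_fold_mean(self, fixture_set, quick_cv):
        cfg = ScenarioConfig(
            cv=quick_cv,
            backbones=("mobilenet",),
            classifiers=[ClassifierSpec(k) for k in
                         ("svm_linear", "svm_cubic", "knn1", "lda",
                          "subspace_discriminant_ensemble")],
        )
        report = run_scenario("II", fixture_set, cfg)
        assert len(report.results) == 5
        for r in report.results:
            assert len(r.folds) == 10
            assert abs(r.mean_accuracy - np.mean([f.accuracy for f in r.folds])) < 1e-12
        assert report.leakage_audit == "passed"

    def test_scenario_iii_runs_with_detail_features(self, fixture_set, quick_cv):
        cfg = ScenarioConfig(cv=quick_cv, backbones=("densenet201",),
                             classifiers=[ClassifierSpec("lda")])
        report = run_scenario("III", fixture_set, cfg)
        (res,) = report.results
        assert res.name == "densenet201/lda"
        assert res.mean_accuracy > 0.2  # above 5-class chance
        assert res.pooled_confusion.sum() == 2 * len(fixture_set)

    def test_scenario_iv_fixed_dimension(self, fixture_set, quick_cv):
        cfg = ScenarioConfig(cv=quick_cv, fusion_method="pca", fusion_n=5,
                             classifiers=[ClassifierSpec("lda")])
        report = run_scenario("IV", fixture_set, cfg)
        assert report.results[0].mean_accuracy > 0.9
        assert report.search_profiles == {}

    def test_scenario_i_requires_two_or_four_classes(self, fixture_set, quick_cv):
        cfg = ScenarioConfig(cv=quick_cv, backbones=("mobilenet",))
        with pytest.raises(ConfigurationError):
            run_scenario("I", fixture_set, cfg)

    def test_scenario_i_end_to_end_binary(self, fixture_set):
        from mbhis import make_binary_level

        binary = make_binary_level(fixture_set, n_abnormal=10, seed=0)
        cfg = ScenarioConfig(
            cv=CVConfig(k=2, repeats=1, base_seed=0),
            backbones=("mobilenet",),
            train=TrainConfig(epochs=5, seed=0),
        )
        report = run_scenario("I", binary, cfg)
        (res,) = report.results
        assert len(res.folds) == 2
        assert res.pooled_confusion.sum() == len(binary)

    def test_augmentation_stays_in_training_folds(self, fixture_set):
        small = fixture_set.subset(range(0, 50, 2))  # 5 per class
        cfg = ScenarioConfig(
            cv=CVConfig(k=2, repeats=1, base_seed=0),
            backbones=("mobilenet",),
            classifiers=[ClassifierSpec("lda")],
            augmentation=AugmentationPolicy(per_image_copies=1, seed=0),
        )
        report = run_scenario("II", small, cfg)
        assert report.leakage_audit == "passed"
        assert report.results[0].pooled_confusion.sum() == len(small)

    def test_unknown_scenario_rejected(self, fixture_set, quick_cv):
        with pytest.raises(ConfigurationError):
            run_scenario("V", fixture_set, ScenarioConfig(cv=quick_cv))

    def test_report_round_trips_to_json(self, fixture_set, quick_cv, tmp_path):
        import json

        cfg = ScenarioConfig(cv=quick_cv, backbones=("mobilenet",),
                             classifiers=[ClassifierSpec("knn1")])
        report = run_scenario("II", fixture_set, cfg)
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["scenario"] == "II"
        assert len(loaded["results"][0]["folds"]) == 10
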