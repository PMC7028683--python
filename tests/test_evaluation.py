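"""One-vs-rest metrics, subject-wise folds, cross-validation, latency."""

import numpy as np
import pytest

import prefall as pf
from prefall.errors import (
    DataError,
    MeasurementError,
    SplitError,
    UndefinedMetricError,
)


class TestConfusionCounts:
    def test_perfect_prediction_has_no_errors(self):
        y = np.array([0, 1, 2, 1, 0])
        for cls in (0, 1, 2):
            c = pf.confusion_counts(y, y, cls)
            assert c.fn == 0 and c.fp == 0

    def test_hand_enumerated_example(self):
        y_true = np.array([0, 0, 1, 2])
        y_pred = np.array([0, 1, 1, 2])
        c = pf.confusion_counts(y_true, y_pred, 0)
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 2, 0)

    def test_counts_partition_every_instance(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 50)
        y_pred = rng.integers(0, 3, 50)
        for cls in (0, 1, 2):
            assert pf.confusion_counts(y_true, y_pred, cls).total == 50

    def test_label_outside_three_classes_rejected(self):
        with pytest.raises(DataError):
            pf.confusion_counts(np.array([0, 3]), np.array([0, 1]), 0)


class TestClassMetrics:
    def test_direct_arithmetic_example(self):
        m = pf.class_metrics(pf.ConfusionCounts(0, tp=1, fn=1, tn=2, fp=0))
        assert (m.sensitivity, m.specificity, m.accuracy) == (0.5, 1.0, 0.75)

    def test_perfect_counts_give_unit_metrics(self):
        m = pf.class_metrics(pf.ConfusionCounts(1, tp=10, fn=0, tn=30, fp=0))
        assert m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_zero_denominator_names_the_class(self):
        with pytest.raises(UndefinedMetricError, match="pre-impact"):
            pf.class_metrics(pf.ConfusionCounts(1, tp=0, fn=0, tn=5, fp=1))

    def test_agreement_with_sklearn_on_random_vectors(self):
        """Independent library oracle over many random label vectors."""
        from sklearn.metrics import multilabel_confusion_matrix

        rng = np.random.default_rng(1)
        for _ in range(200):
            y_true = rng.integers(0, 3, 60)
            y_pred = rng.integers(0, 3, 60)
            mcm = multilabel_confusion_matrix(y_true, y_pred, labels=[0, 1, 2])
            for cls in (0, 1, 2):
                (tn, fp), (fn, tp) = mcm[cls]
                c = pf.confusion_counts(y_true, y_pred, cls)
                assert (c.tp, c.fn, c.tn, c.fp) == (tp, fn, tn, fp)
                m = pf.class_metrics(c)
                assert abs(m.sensitivity - tp / (tp + fn)) < 1e-12
                assert abs(m.specificity - tn / (tn + fp)) < 1e-12


ELDERLY = [f"SE{i:02d}" for i in range(1, 16)]
YOUNG = [f"SA{i:02d}" for i in range(1, 24)]


class TestSubjectwiseFolds:
    def test_canonical_geometry(self):
        folds = pf.make_subjectwise_folds(ELDERLY, YOUNG, rng=0)
        sizes = sorted(len(f.test_subjects) for f in folds)
        assert sizes == [7, 7, 8, 8, 8]
        for f in folds:
            n_elderly = sum(s.startswith("SE") for s in f.test_subjects)
            assert n_elderly == 3

    def test_partition_invariants_over_many_seeds(self):
        for seed in range(50):
            folds = pf.make_subjectwise_folds(ELDERLY, YOUNG, rng=seed)
            seen = []
            for f in folds:
                assert not set(f.test_subjects) & set(f.train_subjects)
                assert set(f.test_subjects) | set(f.train_subjects) == \
                    set(ELDERLY) | set(YOUNG)
                seen.extend(f.test_subjects)
            assert sorted(seen) == sorted(ELDERLY + YOUNG)

    def test_train_fraction_close_to_eighty_percent(self):
        folds = pf.make_subjectwise_folds(ELDERLY, YOUNG, rng=3)
        for f in folds:
            ratio = len(f.train_subjects) / 38
            assert 0.78 <= ratio <= 0.82

    def test_too_few_elderly_rejected(self):
        with pytest.raises(SplitError):
            pf.make_subjectwise_folds(ELDERLY[:4], YOUNG, rng=0)


@pytest.fixture(scope="module")
def small_cv_report():
    cfg = pf.SimCohortConfig(n_young=5, n_elderly=5, trials_per_subject=1, seed=21)
    cohort = pf.simulate_cohort(cfg)
    model_cfg = pf.ModelConfig.cnn(width=8, fc_hidden=16)
    report = pf.cross_validate(
        cohort, model_cfg, pf.TrainConfig(n_epochs=1, seed=0),
        n_folds=5, fold_seed=1, pooled=True,
    )
    return cohort, report


class TestCrossValidate:
    def test_report_structure_five_folds_three_classes(self, small_cv_report):
        _, report = small_cv_report
        assert len(report["folds"]) == 5
        for fold in report["folds"]:
            assert set(fold["metrics"]) == {"non-fall", "pre-impact", "fall"}
            for metrics in fold["metrics"].values():
                assert set(metrics) == {"sensitivity", "specificity", "accuracy"}
        assert set(report["mean"]) == {"non-fall", "pre-impact", "fall"}
        assert set(report["pooled"]) == {"non-fall", "pre-impact", "fall"}

    def test_no_subject_leaks_between_train_and_test(self, small_cv_report):
        cohort, report = small_cv_report
        seen = []
        for fold in report["folds"]:
            seen.extend(fold["test_subjects"])
        assert sorted(seen) == sorted(cohort.subject_ids)

    def test_mean_is_average_of_defined_fold_values(self, small_cv_report):
        _, report = small_cv_report
        for cls in ("non-fall", "pre-impact", "fall"):
            vals = [f["metrics"][cls]["sensitivity"] for f in report["folds"]
                    if f["metrics"][cls]["sensitivity"] is not None]
            assert report["mean"][cls]["sensitivity"] == pytest.approx(np.mean(vals))


class _IdentityStub:
    """Cheapest possible 'model': a fixed probability row per instance."""

    def predict_proba(self, x):
        return np.tile([1.0, 0.0, 0.0], (len(x), 1))


class TestLatency:
    def test_requires_at_least_100_instances(self):
        with pytest.raises(MeasurementError):
            pf.measure_latency(_IdentityStub(), np.zeros((50, 256, 6)))

    def test_real_model_slower_than_identity_stub(self, default_dataset):
        x = default_dataset.windows[:120]
        model = pf.build_cnn(pf.ModelConfig.cnn(width=16, fc_hidden=32), seed=0)
        real = pf.measure_latency(model, x)
        stub = pf.measure_latency(_IdentityStub(), x)
        assert real["mean_ms"] > 0
        assert stub["mean_ms"] < real["mean_ms"]

    def test_repeated_measurement_is_stable_after_warmup(self, default_dataset):
        # a production-size model: per-instance cost large enough that
        # interpreter jitter stays a fraction of it
        x = default_dataset.windows[:150]
        model = pf.build_cnn(seed=0)
        r = pf.measure_latency(model, x, n_warmup=20)
        assert r["std_ms"] / r["mean_ms"] < 0.5
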