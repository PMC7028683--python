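"""Focal loss, the training loop contract and epoch selection."""

import numpy as np
import pytest

import prefall as pf
from prefall.errors import SelectionError, TrainingDataError
from prefall.training import (
    EpochRecord,
    _focal_loss_grad,
    inverse_frequency_alpha,
)


def random_batch(rng, b=32, k=3):
    logits = rng.normal(size=(b, k))
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    labels = rng.integers(0, k, size=b)
    return probs, labels


def cross_entropy_oracle(probs, labels):
    """Straight textbook mean negative log-likelihood."""
    total = 0.0
    for i, lab in enumerate(labels):
        total += -np.log(probs[i, lab])
    return total / len(labels)


class TestFocalLoss:
    def test_perfectly_confident_batch_has_zero_loss(self):
        probs = np.eye(3)[[0, 1, 2, 1]]
        assert pf.focal_loss(probs, np.array([0, 1, 2, 1]), gamma=2.0) == 0.0

    def test_reduces_to_cross_entropy_at_gamma_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            probs, labels = random_batch(rng)
            fl = pf.focal_loss(probs, labels, gamma=0.0, alpha=1.0)
            assert abs(fl - cross_entropy_oracle(probs, labels)) < 1e-6

    def test_gamma_downweights_well_classified_batch(self):
        rng = np.random.default_rng(1)
        b = 16
        labels = rng.integers(0, 3, size=b)
        probs = np.full((b, 3), 0.04)
        probs[np.arange(b), labels] = 0.92  # every sample well classified
        losses = [pf.focal_loss(probs, labels, gamma=g) for g in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(a > b_ for a, b_ in zip(losses, losses[1:]))

    def test_zero_probability_is_clamped_never_nan(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        loss = pf.focal_loss(probs, np.array([1]), gamma=2.0)
        assert np.isfinite(loss) and loss > 0

    def test_loss_invariant_to_sample_order(self):
        rng = np.random.default_rng(2)
        probs, labels = random_batch(rng)
        perm = rng.permutation(len(labels))
        a = pf.focal_loss(probs, labels, gamma=2.0, alpha=(0.5, 1.5, 1.0))
        b = pf.focal_loss(probs[perm], labels[perm], gamma=2.0, alpha=(0.5, 1.5, 1.0))
        assert abs(a - b) < 1e-12

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        probs, labels = random_batch(rng, b=6)
        for gamma in (0.0, 2.0):
            _, grad = _focal_loss_grad(probs, labels, gamma, (0.7, 1.2, 1.1))
            eps = 1e-7
            for i in range(probs.shape[0]):
                j = labels[i]
                p1 = probs.copy(); p1[i, j] += eps
                p2 = probs.copy(); p2[i, j] -= eps
                num = (pf.focal_loss(p1, labels, gamma, (0.7, 1.2, 1.1))
                       - pf.focal_loss(p2, labels, gamma, (0.7, 1.2, 1.1))) / (2 * eps)
                assert abs(grad[i, j] - num) < 1e-5

    def test_inverse_frequency_alpha_mean_one(self):
        labels = np.array([0] * 70 + [1] * 10 + [2] * 20)
        a = inverse_frequency_alpha(labels)
        assert abs(a.mean() - 1.0) < 1e-12
        assert a[1] > a[2] > a[0]


def record(epoch, sens):
    return EpochRecord(epoch=epoch, train_loss=0.0, test_loss=0.0,
                       train_sensitivity=sens, test_sensitivity=sens)


class TestEpochSelection:
    def test_worked_example_top3_then_nonfall_plus_pre(self):
        # totals [2.7, 2.8, 2.9, 2.85], nonfall+pre [1.8, 1.9, 1.85, 1.95]
        records = [
            record(0, (0.9, 0.9, 0.9)),
            record(1, (0.95, 0.95, 0.9)),
            record(2, (0.9, 0.95, 1.05)),
            record(3, (1.0, 0.95, 0.9)),
        ]
        assert pf.select_best_epoch(records) == 3

    def test_single_epoch_returned(self):
        assert pf.select_best_epoch([record(4, (0.5, 0.5, 0.5))]) == 4

    def test_all_identical_breaks_tie_to_earliest(self):
        records = [record(i, (0.8, 0.8, 0.8)) for i in range(6)]
        assert pf.select_best_epoch(records) == 0

    def test_empty_history_rejected(self):
        with pytest.raises(SelectionError):
            pf.select_best_epoch([])

    def test_agrees_with_brute_force_on_random_histories(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            records = [record(i, tuple(rng.uniform(0, 1, 3))) for i in range(n)]
            # brute force: enumerate all epochs, rank exactly as specified
            totals = [sum(r.test_sensitivity) for r in records]
            top3 = sorted(range(n), key=lambda i: (-totals[i], i))[:3]
            best = min(
                top3,
                key=lambda i: (-(records[i].test_sensitivity[0]
                                 + records[i].test_sensitivity[1]), i),
            )
            got = pf.select_best_epoch(records)
            assert got == best
            assert got in top3  # selection always lies in the top-3 set


@pytest.fixture(scope="module")
def tiny_sets():
    """A small separable window set split by subject."""
    cfg = pf.SimCohortConfig(n_young=2, n_elderly=1, trials_per_subject=1, seed=11)
    cohort = pf.simulate_cohort(cfg)
    ds = pf.build_dataset(cohort.trials)
    train = ds.for_subjects(["SA01", "SE01"])
    test = ds.for_subjects(["SA02"])
    return train, test


class TestTrainModel:
    def test_zero_epochs_returns_empty_history_and_untouched_model(self, tiny_sets):
        train, test = tiny_sets
        model = pf.build_cnn(pf.ModelConfig.cnn(width=8, fc_hidden=16), seed=0)
        before = [p.data.copy() for p in model.params()]
        records = pf.train_model(model, train, test, pf.TrainConfig(n_epochs=0))
        assert records == []
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_same_seed_gives_identical_histories(self, tiny_sets):
        train, test = tiny_sets
        cfg = pf.TrainConfig(n_epochs=2, seed=5)
        out = []
        for _ in range(2):
            model = pf.build_cnn(pf.ModelConfig.cnn(width=8, fc_hidden=16), seed=1)
            out.append(pf.train_model(model, train, test, cfg))
        for ra, rb in zip(*out):
            assert ra.train_loss == rb.train_loss
            assert ra.test_loss == rb.test_loss
            assert ra.train_sensitivity == rb.train_sensitivity
            assert ra.test_sensitivity == rb.test_sensitivity
            assert ra.test_counts == rb.test_counts

    def test_missing_class_in_train_set_rejected(self, tiny_sets):
        train, test = tiny_sets
        adl_only = train.subset(train.labels == 0)
        model = pf.build_cnn(pf.ModelConfig.cnn(width=8, fc_hidden=16), seed=0)
        with pytest.raises(TrainingDataError):
            pf.train_model(model, adl_only, test, pf.TrainConfig(n_epochs=1))

    def test_records_carry_consistent_counts(self, tiny_sets):
        train, test = tiny_sets
        model = pf.build_cnn(pf.ModelConfig.cnn(width=8, fc_hidden=16), seed=2)
        records = pf.train_model(model, train, test, pf.TrainConfig(n_epochs=1, seed=2))
        rec = records[0]
        for cls in (0, 1, 2):
            tp, fn, tn, fp = rec.test_counts[cls]
            assert tp + fn + tn + fp == len(test)
            n_cls = int((test.labels == cls).sum())
            assert tp + fn == n_cls
            if n_cls:
                assert abs(rec.test_sensitivity[cls] - tp / n_cls) < 1e-12
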