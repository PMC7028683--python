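"""Synthetic cohort generator: phase structure, annotations, separability."""

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import periodogram

import prefall as pf
from prefall.errors import ConfigError
from prefall.simulate import (
    DEFAULT_ADL_TEMPLATES,
    DEFAULT_FALL_TEMPLATES,
    simulate_adl_trial,
    simulate_fall_trial,
)

TPL = {t.name: t for t in DEFAULT_ADL_TEMPLATES}
FALL_TPL = {t.name: t for t in DEFAULT_FALL_TEMPLATES}


def acc_magnitude(trial):
    return np.linalg.norm(trial.samples[:, :3], axis=1)


class TestAdlTrials:
    def test_stand_zero_noise_is_pure_gravity(self, quiet_config, subject, rng):
        trial, _ = simulate_adl_trial(TPL["stand"], subject, rng, quiet_config)
        np.testing.assert_allclose(acc_magnitude(trial), 1.0, atol=1e-12)

    def test_walk_spectral_peak_at_cadence(self, quiet_config, subject, rng):
        trial, _ = simulate_adl_trial(TPL["walk"], subject, rng, quiet_config)
        f, pxx = periodogram(trial.samples[:, 2] - 1.0, fs=trial.rate_hz)
        assert abs(f[np.argmax(pxx)] - subject.cadence_hz) < 0.2

    @pytest.mark.parametrize("name", ["walk", "stand", "jog", "sit_down"])
    def test_magnitude_envelope_within_adl_bounds(self, name, quiet_config,
                                                  subject, rng):
        trial, _ = simulate_adl_trial(TPL[name], subject, rng, quiet_config)
        mag = acc_magnitude(trial)
        assert mag.min() >= 0.5 and mag.max() <= 2.5

    def test_annotation_marks_whole_trial_non_fall(self, subject, rng):
        trial, ann = simulate_adl_trial(TPL["walk"], subject, rng)
        assert ann.is_adl
        assert ann.fall_end == trial.n_samples

    def test_unknown_template_rejected(self, subject, rng):
        from prefall.simulate import AdlTemplate

        with pytest.raises(ConfigError):
            simulate_adl_trial(AdlTemplate("cartwheel", "D99"), subject, rng)


class TestFallTrials:
    def test_free_fall_floor_and_impact_peak(self, quiet_config, subject, rng):
        trial, ann = simulate_fall_trial(FALL_TPL["forward"], subject, rng,
                                         quiet_config)
        mag = acc_magnitude(trial)
        assert mag[ann.pre_impact_start:ann.pre_impact_end].min() < 0.8
        assert mag[ann.pre_impact_end:ann.fall_end].max() > 2.0

    @pytest.mark.parametrize("name", list(FALL_TPL))
    def test_descent_duration_within_template_range(self, name, subject, rng):
        tpl = FALL_TPL[name]
        trial, ann = simulate_fall_trial(tpl, subject, rng)
        dur_ms = (ann.pre_impact_end - ann.pre_impact_start) / trial.rate_hz * 1e3
        lo, hi = tpl.descent_ms
        assert lo - 5 <= dur_ms <= hi + 5  # rounding to whole samples

    def test_rotation_burst_starts_at_pre_impact_onset(self, quiet_config,
                                                       subject, rng):
        tpl = FALL_TPL["forward"]
        trial, ann = simulate_fall_trial(tpl, subject, rng, quiet_config)
        gyro = np.abs(trial.samples[:, 3 + tpl.gyro_axis])
        # walking sway stays small; within 50 ms of onset the burst dominates
        k = int(0.05 * trial.rate_hz)
        assert gyro[ann.pre_impact_start + k] > 60.0
        assert gyro[: ann.pre_impact_start].max() < 60.0

    def test_fixed_seed_reproduces_trial_exactly(self, subject):
        a, _ = simulate_fall_trial(FALL_TPL["lateral"], subject,
                                   np.random.default_rng(5))
        b, _ = simulate_fall_trial(FALL_TPL["lateral"], subject,
                                   np.random.default_rng(5))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_annotation_indices_are_consistent(self, subject, rng):
        trial, ann = simulate_fall_trial(FALL_TPL["backward"], subject, rng)
        ann.validate(trial.n_samples)
        assert 0 < ann.pre_impact_start < ann.pre_impact_end < ann.fall_end
        assert ann.fall_end < trial.n_samples  # post-fall tail to truncate


class TestCohort:
    def test_sisfall_scale_cohort_has_38_subjects(self):
        cfg = pf.SimCohortConfig(n_young=23, n_elderly=15, trials_per_subject=0)
        cohort = pf.simulate_cohort(cfg)
        assert len(cohort.subjects) == 38
        assert len(cohort.ids_by_group("elderly")) == 15

    def test_empty_cohort_is_valid(self):
        cohort = pf.simulate_cohort(pf.SimCohortConfig(n_young=0, n_elderly=0))
        assert cohort.subjects == [] and cohort.trials == []

    def test_trial_count_conservation(self, default_cohort):
        cfg = default_cohort.config
        n_templates = len(cfg.fall_templates) + len(cfg.adl_templates)
        expected = (cfg.n_young + cfg.n_elderly) * cfg.trials_per_subject * n_templates
        assert len(default_cohort.trials) == expected

    def test_same_seed_same_cohort(self):
        cfg = pf.SimCohortConfig(n_young=1, n_elderly=1, trials_per_subject=1, seed=9)
        a = pf.simulate_cohort(cfg)
        b = pf.simulate_cohort(cfg)
        for (ta, _), (tb, _) in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.samples, tb.samples)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConfigError):
            pf.SimCohortConfig(impact_peak_range=(1.5, 6.0))
        with pytest.raises(ConfigError):
            pf.SimCohortConfig(freefall_floor_range=(0.2, 0.9))

    def test_threshold_rule_separates_falls_from_adls(self, default_cohort):
        """Free-fall floor then impact peak: a two-threshold rule must get
        > 99% of trials right, guaranteeing the learning task is solvable."""
        correct = 0
        for trial, ann in default_cohort.trials:
            cut = pf.truncate_post_fall(trial, ann)
            mag = np.linalg.norm(cut.samples[:, :3], axis=1)
            w = int(0.3 * trial.rate_hz)
            mins = sliding_window_view(mag, w).min(axis=1)
            i = int(mins.argmin())
            is_fall = bool(mins[i] < 0.8 and mag[i:].max() > 2.0)
            correct += is_fall == trial.is_fall_activity
        assert correct / len(default_cohort.trials) > 0.99


def test_cohort_disk_roundtrip(tmp_path):
    cfg = pf.SimCohortConfig(n_young=1, n_elderly=1, trials_per_subject=1, seed=3)
    cohort = pf.simulate_cohort(cfg)
    pf.write_cohort(cohort, tmp_path)
    back = pf.load_cohort(tmp_path)
    assert len(back.trials) == len(cohort.trials)
    assert back.subject_ids == cohort.subject_ids
    for (ta, aa), (tb, ab) in zip(
        sorted(cohort.trials, key=lambda p: (p[0].activity_code, p[0].subject_id, p[0].trial_index)),
        sorted(back.trials, key=lambda p: (p[0].activity_code, p[0].subject_id, p[0].trial_index)),
    ):
        assert aa == ab
        # quantized to the ADC grid on write
        np.testing.assert_allclose(ta.samples[:, :3], tb.samples[:, :3], atol=2e-3)
        np.testing.assert_allclose(ta.samples[:, 3:], tb.samples[:, 3:], atol=4e-2)
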