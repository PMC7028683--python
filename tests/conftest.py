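import numpy as np
import pytest

import prefall as pf


@pytest.fixture(scope="session")
def default_cohort() -> pf.Cohort:
    """The default desk-scale synthetic cohort (fixed seed)."""
    return pf.simulate_cohort(pf.SimCohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_dataset(default_cohort) -> pf.WindowSet:
    return pf.build_dataset(default_cohort.trials)


@pytest.fixture(scope="session")
def fold0_split(default_cohort, default_dataset):
    """Train/test window sets for the first canonical subject-wise fold."""
    folds = pf.make_subjectwise_folds(
        default_cohort.ids_by_group("elderly"),
        default_cohort.ids_by_group("young"),
        rng=0,
        n_folds=5,
    )
    split = folds[0]
    return (
        default_dataset.for_subjects(split.train_subjects),
        default_dataset.for_subjects(split.test_subjects),
    )


@pytest.fixture(scope="session")
def quiet_config() -> pf.SimCohortConfig:
    """Noise-free generator settings for kinematic-template assertions."""
    return pf.SimCohortConfig(noise_sd_acc=0.0, noise_sd_gyro=0.0, seed=0)


@pytest.fixture()
def subject() -> "pf.simulate.SubjectParams":
    from prefall.simulate import SubjectParams

    return SubjectParams(subject_id="SA01", group="young", gain=1.0,
                         cadence_hz=1.8, jitter=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
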