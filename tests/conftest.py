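import numpy as np
import pytest

from oncosensi import cohort_stats, table1


@pytest.fixture(scope="session")
def cohort():
    return table1.table1_fixture()


@pytest.fixture(scope="session")
def test_set(cohort):
    return table1.test_set(cohort)


@pytest.fixture(scope="session")
def validation_set(cohort):
    return table1.validation_set(cohort)


@pytest.fixture(scope="session")
def frozen_stats(test_set):
    """Reference statistics frozen on the 14-patient test set."""
    return cohort_stats.freeze_reference(test_set)


@pytest.fixture(scope="session")
def test_z(test_set, frozen_stats):
    """Z-score columns (z_rt_auc, z_growth_rate, z_hpv) of the test set."""
    return cohort_stats.standardize_cohort(test_set, frozen_stats)


@pytest.fixture(scope="session")
def recurrence_labels(test_set):
    return (test_set["recur"] == "yes").to_numpy().astype(int)
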