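import pytest

import rivapk as rp
from rivapk.estimate import FitConfig


@pytest.fixture(scope="session")
def table2():
    """Published final-model parameterization."""
    return rp.PopParams()


@pytest.fixture(scope="session")
def study_ds(table2):
    """One synthetic replicate of the 60-patient crossover study."""
    return rp.simulate_study(rp.CohortConfig(), table2, seed=101)


@pytest.fixture(scope="session")
def study_fit(study_ds):
    """Final-model fit (with standard errors) on the study replicate."""
    return rp.fit(study_ds)


@pytest.fixture()
def fast_cfg():
    return FitConfig(compute_se=False)
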