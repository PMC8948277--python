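import numpy as np
import pytest

from connfp import (
    CohortParams,
    CPMConfig,
    differential_power,
    run_cpm,
    simulate_cohort,
    threshold_percentile,
)

# Reference study conditions: 40 subjects, 60 nodes (1770 edges), 1% planted
# identity edges (SD 0.5), 1% behaviour edges (SD 0.1), background SD 0.05,
# session noise SD 0.075.  Several deep tests share this cohort and the CPM
# run on it, so they are session-scoped.


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortParams(seed=11))


@pytest.fixture(scope="session")
def default_dp(default_cohort):
    cset = default_cohort.connectomes
    return differential_power(cset.session(0), cset.session(1))


@pytest.fixture(scope="session")
def default_dp_mask(default_dp):
    return threshold_percentile(default_dp.values, pct=99)


@pytest.fixture(scope="session")
def default_cpm(default_cohort):
    cset = default_cohort.connectomes
    y = default_cohort.behaviours["score1"].to_numpy(float)
    return run_cpm(cset.session_mean(), y, CPMConfig(seed=11), subjects=cset.subjects)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
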