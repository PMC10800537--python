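import numpy as np
import pytest

from mixmediate.scenarios import builtin_scenarios, generate_cohort

PBDE6 = ["pbde_28", "pbde_47", "pbde_99", "pbde_100", "pbde_153", "pbde_154"]


@pytest.fixture(scope="session")
def catalog():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def s1_cohort(catalog):
    """One large S1 cohort shared by recovery tests."""
    return generate_cohort(catalog["S1"], 200_000, seed=1)


@pytest.fixture(scope="session")
def s1b_cohort(catalog):
    return generate_cohort(catalog["S1b"], 200_000, seed=3)


@pytest.fixture(scope="session")
def s4_cohort_small(catalog):
    return generate_cohort(catalog["S4"], 20_000, seed=13)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
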