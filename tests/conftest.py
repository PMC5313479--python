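import pytest

from casco import CohortParams, load_instrument, simulate_cohort


@pytest.fixture(scope="session")
def casco_inst():
    return load_instrument("casco")


@pytest.fixture(scope="session")
def mini_inst():
    return load_instrument("minicasco")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort (186 patients + 95 controls), fixed seed."""
    return simulate_cohort(CohortParams(seed=11))
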