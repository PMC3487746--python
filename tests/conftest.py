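import pytest

from pcriterion import (
    MU_PRESETS,
    PopulationParams,
    compute_nu,
    load_reference_catalog,
)


@pytest.fixture(scope="session")
def params():
    """Default prevalence/selection parameters (p=1.29e-2, s=0.654)."""
    return PopulationParams()


@pytest.fixture(scope="session")
def nu_highest(params):
    """Threshold at the parental-age-scaled highest mutation rate."""
    return compute_nu(params, MU_PRESETS["highest"])


@pytest.fixture(scope="session")
def nu_average(params):
    return compute_nu(params, MU_PRESETS["average"])


@pytest.fixture(scope="session")
def reference_catalog():
    """The packaged 64-row candidate-gene catalog."""
    return load_reference_catalog()
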