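import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from firebiorisk import generate_scenario, table1_fixture

#: landscape species totals of the packaged table
TOTALS = (3260, 2412, 1437)

#: printed per-unit index columns (diversity, vulnerability, loss); the
#: maquis diversity values correspond to the SES-swapped table variant
PRINTED = {
    "dhf_calcareous": (0.000075, 0.6, 0.000045),
    "dhf_ultramafic": (0.00072, 3.3, 0.002376),
    "dhf_sed_volcanic": (0.00038, 0.65, 0.000247),
    "maquis_mid_low": (0.00022, 0.05, 0.000011),
    "maquis_high": (0.0034, 0.08, 0.000272),
    "sclerophyll": (0.0053, 15.8, 0.08374),
    "savanna": (0.000027, 0.0, 0.0),
}


@pytest.fixture(scope="session")
def table_swapped():
    return table1_fixture("ses_swapped")


@pytest.fixture(scope="session")
def table_printed():
    return table1_fixture("as_printed")


@pytest.fixture(scope="session")
def nc_bundle():
    """A small fixed nc-like scenario shared across read-only tests."""
    return generate_scenario("nc_like", seed=11, nrows=30, ncols=30)
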