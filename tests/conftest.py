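import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clinekit as ck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# Standard simulated-transect conditions used across fitting tests:
# 30 populations spanning four cline widths around the center.
TRUE_CLINE = ck.ClineParams(c=50.0, w=8.0)
POSITIONS = np.linspace(34.0, 66.0, 30)


@pytest.fixture(scope="session")
def true_cline():
    return TRUE_CLINE


@pytest.fixture(scope="session")
def positions():
    return POSITIONS


def simulate_locus(seed, *, params=TRUE_CLINE, n_alleles=80, positions=POSITIONS, label="A"):
    cfg = ck.ZoneSimConfig(loci={label: params}, positions=positions, n_alleles=n_alleles, seed=seed)
    return ck.simulate_zone(cfg)[label]


@pytest.fixture(scope="session")
def sim_dataset():
    """One representative simulated dataset (30 pops, n=80 alleles)."""
    return simulate_locus(seed=11)


@pytest.fixture(scope="session")
def sim_fit8(sim_dataset):
    return ck.fit_cline(sim_dataset, ck.ModelSpec.eight_parameter(), n_starts=12, seed=11)
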