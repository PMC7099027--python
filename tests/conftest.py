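import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from strawtrace import IsotopeEndMembers, SimulationConfig, StrawAmendment

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def end():
    """Study end members: unamended soil vs enriched wheat straw."""
    return IsotopeEndMembers(delta_soil=-27.78, delta_straw=357.48)


@pytest.fixture(scope="session")
def straw():
    """30 g enriched wheat straw per kg soil (352.9 g C, 6.38 g N per kg)."""
    return StrawAmendment(straw_per_soil=30.0, c_content=352.9,
                          total_n=6.38, delta=357.48)


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def noisefree_cfg(default_cfg):
    return dataclasses.replace(default_cfg, noise_delta_sd=0.0,
                               noise_c_rel_sd=0.0)


@pytest.fixture(scope="session")
def fast_cfg():
    """Reduced design for quick end-to-end runs."""
    return SimulationConfig(schedule=(7, 60), n_rep=2, n_taxa=10,
                            n_coupled=4, library_size=3000, seed=11)
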