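import pytest

from pdi_multiverse import (
    default_grouping,
    generate_cohort,
    apply_eligibility,
    resolve_diet_exposure,
)
from pdi_multiverse.simulate import SimulationParams


@pytest.fixture(scope="session")
def base_config():
    return default_grouping()


@pytest.fixture(scope="session")
def small_cohort():
    """An 800-participant cohort with the default (null-effect) parameters."""
    params = SimulationParams(n_participants=800)
    return generate_cohort(params, seed=7)


@pytest.fixture(scope="session")
def resolved_cohort(small_cohort):
    """The small cohort after eligibility filtering and exposure resolution."""
    eligible, _ = apply_eligibility(small_cohort)
    return resolve_diet_exposure(eligible)
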