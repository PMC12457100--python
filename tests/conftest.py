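import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gliotwin import (
    CohortSpec,
    DEFAULT_FRACTIONS,
    ModelParams,
    PopulationState,
    allocate_initial_state,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """Default fixed-parameter set with the control-group killing rate."""
    return ModelParams().for_group("control")


@pytest.fixture(scope="session")
def treated_params() -> ModelParams:
    """Treated-group preset: IR-group killing rate and a proliferation
    coefficient in the regime of the larger treated tumors."""
    return ModelParams(rho_T=5.0e-6).for_group("treated")


@pytest.fixture(scope="session")
def control_initial(params) -> PopulationState:
    """A 3 mm^3 control tumor split with the experimental fractions."""
    return allocate_initial_state(3.0, DEFAULT_FRACTIONS, params)


@pytest.fixture(scope="session")
def treated_initial(treated_params) -> PopulationState:
    """A 41.5 mm^3 tumor (treated-group mean initial volume)."""
    return allocate_initial_state(41.5, DEFAULT_FRACTIONS, treated_params)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Deterministic noise-free cohort (4 control + 10 treated) with truth."""
    from gliotwin import generate_cohort

    spec = CohortSpec(seed=2024, noise_sigma=0.0)
    records, truth = generate_cohort(spec)
    return spec, records, truth
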