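import numpy as np
import pytest

from riskmom import PopulationModel, SimConfig, cohort_to_frame, generate_cohort
from riskmom import defaults


@pytest.fixture(scope="session")
def unaffected_params():
    return defaults.default_unaffected()


@pytest.fixture(scope="session")
def affected_params():
    return defaults.default_affected("<=5y")


@pytest.fixture(scope="session")
def incidence5():
    return defaults.default_incidence(horizon=5.0)


@pytest.fixture(scope="session")
def population(affected_params, unaffected_params, incidence5):
    return PopulationModel(
        affected=affected_params,
        unaffected=unaffected_params,
        prior=incidence5,
        ages=defaults.SCREEN_AGES,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate synthetic cohort at the default study conditions."""
    cfg = SimConfig(n_cases=400, seed=20240)
    return cohort_to_frame(generate_cohort(cfg))


@pytest.fixture(scope="session")
def single_band_cohort():
    """Cohort with every case in the 0-5 year band (dense short follow-up)."""
    cfg = SimConfig(
        n_cases=400,
        band_probs={"0-5": 1.0},
        seed=777,
    )
    return cohort_to_frame(generate_cohort(cfg))
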