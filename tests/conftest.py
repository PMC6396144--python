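import numpy as np
import pytest

from tafsim import CohortDesign, ModelSpec, generate_cohort


@pytest.fixture
def stress_model():
    return ModelSpec(mechanism="stress", lambda_T=0.05, lambda_N=7.0, rho=2.0,
                     horizon_months=30.0)


@pytest.fixture
def proliferation_model():
    return ModelSpec(
        mechanism="proliferation",
        delta_c=-np.log(0.85) / 27.0,
        mu_d=2.0,
        horizon_months=30.0,
    )


@pytest.fixture
def stress_cohort(stress_model):
    return generate_cohort(CohortDesign(seed=42), stress_model)
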