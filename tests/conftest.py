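import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort_params():
    """Quarter-scale cohort for fast pipeline tests."""
    from audcog.simulate import CohortParams

    return CohortParams(
        group_sizes={"HIV-negative": 24, "HIV-positive": 44,
                     "TopCATs": 14, "BottomCATs": 20},
        dropout_hazard=0.03,
    )
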