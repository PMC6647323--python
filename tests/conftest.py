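import numpy as np
import pytest
from hypothesis import settings

from aetrial import AccrualPattern, SurvivalModel, TrialDesign

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture
def scenario5_design():
    """Scenario 5 (HR_P=0.50, HR_N=1.43) with (R, F) = (6, 2)."""
    return TrialDesign(recruitment_period=6.0, follow_up=2.0,
                       hr_positive=0.5, hr_negative=1.43)


@pytest.fixture
def survival_model():
    return SurvivalModel(follow_up=2.0, hr_positive=0.5, hr_negative=1.43)


@pytest.fixture
def uniform6():
    return AccrualPattern.uniform(6.0)
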