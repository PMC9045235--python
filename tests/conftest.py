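import numpy as np
import pytest
from hypothesis import settings

import attribwork as aw

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_scenario():
    """Desk-scale scenario with few age bands (fast envelopes)."""
    cfg = aw.ScenarioConfig(seed=5, age_groups=("15-19", "40-44", "65-69", "90+"))
    inputs, truth = aw.generate_scenario(cfg)
    return cfg, inputs, truth


@pytest.fixture(scope="session")
def recovery_scenario():
    """The parameter-recovery scenario: 15 countries, 30 surveys each, n=2000."""
    cfg = aw.ScenarioConfig(seed=7, surveys_per_country=30, survey_sample_size=2000)
    inputs, truth = aw.generate_scenario(cfg)
    return cfg, inputs, truth


@pytest.fixture(scope="session")
def recovery_fit(recovery_scenario):
    cfg, inputs, truth = recovery_scenario
    hierarchy = dict(zip(inputs.hierarchy["iso3"], inputs.hierarchy["region"]))
    fit = aw.fit_prevalence_model(inputs.surveys, hierarchy)
    surface = aw.predict_prevalence(fit)
    return fit, surface


def logit(p):
    return np.log(p) - np.log1p(-p)
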