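import logging
import warnings

import pytest
from hypothesis import HealthCheck, settings

from saltijump.pipeline import RunConfig, analyze_trial
from saltijump.synthetic import paper_like_params, simulate_trial

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("saltijump").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message=".*convergence.*", category=UserWarning)


@pytest.fixture(scope="session")
def male_sim():
    """Noise-free synthetic jump at the male study-condition means."""
    return simulate_trial(paper_like_params("male"))


@pytest.fixture(scope="session")
def female_sim():
    """Noise-free synthetic jump at the female study-condition means."""
    return simulate_trial(paper_like_params("female"))


@pytest.fixture(scope="session")
def male_analysis(male_sim):
    trial, truth = male_sim
    return analyze_trial(trial, RunConfig())


@pytest.fixture(scope="session")
def female_analysis(female_sim):
    trial, truth = female_sim
    return analyze_trial(trial, RunConfig())
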