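import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def cause_config():
    from mcodcvd.classify import CauseSetConfig

    return CauseSetConfig.default()


@pytest.fixture(scope="session")
def small_scenario_frame():
    """~8k deaths from a compact paper-regime-like scenario, classified once."""
    from mcodcvd.classify import CauseSetConfig, classify_frame
    from mcodcvd.synth import ScenarioConfig, generate_deaths

    sc = ScenarioConfig.trend_recovery(seed=11, base_pop=6_000)
    frame = generate_deaths(sc)
    classed = classify_frame(frame, CauseSetConfig.default())
    return sc, frame, classed
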