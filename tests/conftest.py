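import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from crrnaseq.formats_io import PipelineParams, SpacerEndSet
from crrnaseq.simulate import (
    DEFAULT_REFERENCE,
    DEFAULT_REPEAT,
    DEFAULT_SPACERS,
    SimConfig,
)


@pytest.fixture(scope="session")
def repeat() -> str:
    return DEFAULT_REPEAT


@pytest.fixture(scope="session")
def params() -> PipelineParams:
    return PipelineParams(DEFAULT_REPEAT, DEFAULT_REFERENCE, 1.0)


@pytest.fixture(scope="session")
def spacer_ends() -> SpacerEndSet:
    return SpacerEndSet(frozenset(s[-5:] for s in DEFAULT_SPACERS))


@pytest.fixture(scope="session")
def clean_sim_config() -> SimConfig:
    """A moderate error-free run: every pipeline identity should hold exactly."""
    return SimConfig(
        seed=7,
        n_crrna=600,
        n_reference=150,
        n_background=150,
        substitution_rate=0.0,
    )


@pytest.fixture(scope="session")
def clean_sim_run(clean_sim_config):
    from crrnaseq.simulate import simulate_run

    return simulate_run(clean_sim_config)
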