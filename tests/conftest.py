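import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_generator_config():
    from altimir.simulate import GeneratorConfig

    return GeneratorConfig(seed=11, library_size=20_000)


@pytest.fixture(scope="session")
def small_reference(small_generator_config):
    from altimir.simulate import generate_reference

    return generate_reference(small_generator_config)


@pytest.fixture(scope="session")
def small_index(small_reference):
    return small_reference.annotation_index()


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """One shared small synthetic end-to-end run for integration checks."""
    from altimir.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=11, library_size=20_000, n_boot=200)
    return run_pipeline(cfg, out), out
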