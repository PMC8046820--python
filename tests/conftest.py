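import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_cohort():
    """Deterministic cohort built from the reference count table."""
    from hyperchol.synthetic import fixture_from_counts

    return fixture_from_counts()


@pytest.fixture(scope="session")
def fixture_analysis(fixture_cohort):
    """Full pipeline run on the count fixture (no randomness involved)."""
    from hyperchol.pipeline import analyze_cohort

    return analyze_cohort(fixture_cohort, run_variance=False)


@pytest.fixture(scope="session")
def population_50k():
    """Large simulated screening population shared by calibration tests."""
    from hyperchol.synthetic import GeneratorConfig, generate_population

    return generate_population(GeneratorConfig.default(n_population=50_000, seed=987))


@pytest.fixture(scope="session")
def small_population():
    """Small simulated population for pipeline-level tests."""
    from hyperchol.synthetic import GeneratorConfig, generate_population

    return generate_population(GeneratorConfig.default(n_population=2_000, seed=321))
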