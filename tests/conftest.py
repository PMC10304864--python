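import pytest
from hypothesis import HealthCheck, settings

from phage_evo import synthetic_data as sd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_genome() -> sd.FixtureGenome:
    """The bundled 49,223 bp fixture genome (verified on build)."""
    return sd.build_fixture_genome(seed=11)


@pytest.fixture(scope="session")
def annotations_by_population(fixture_genome):
    """Population-level annotations grouped by population label."""
    by_pop = {}
    for a in fixture_genome.population_annotations:
        by_pop.setdefault(a.record.source_id, []).append(a)
    return by_pop


@pytest.fixture(scope="session")
def isolate_annotations_by_population(fixture_genome):
    """Isolate annotations keyed by the isolate's source population."""
    by_pop = {}
    for a in fixture_genome.isolate_annotations:
        pop = sd.ISOLATE_POPULATIONS[a.record.source_id]
        by_pop.setdefault(pop, []).append(a)
    return by_pop
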