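import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rilsim as rs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome_spec():
    return rs.default_genome_spec()


@pytest.fixture(scope="session")
def panel(genome_spec):
    return rs.default_marker_panel(genome_spec)


@pytest.fixture(scope="session")
def marker_by_name(panel):
    return {m.name: m for m in panel}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def f1_hermaphrodite(genome_spec):
    """Completely heterozygous F1 from the AF16-male x HK104-hermaphrodite cross."""
    male = rs.founder("AF16", "male", genome_spec)
    herm = rs.founder("HK104", "hermaphrodite", genome_spec)
    offspring = rs.cross(male, herm, 40, rs.CrossoverModel(),
                         np.random.default_rng(0), genome_spec)
    return next(o for o in offspring if o.is_hermaphrodite)


@pytest.fixture(scope="session")
def study_suite():
    return rs.study_fixture_suite(seed=0)
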