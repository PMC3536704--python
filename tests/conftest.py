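import random

import pytest

from medlsc import ScenarioDB
from medlsc.fixtures import CohortConfig, generate_cohort, paper_db, patientx_db, synthetic_db


@pytest.fixture(scope="session")
def px_db() -> ScenarioDB:
    return patientx_db()


@pytest.fixture(scope="session")
def syn_db() -> ScenarioDB:
    return synthetic_db()


@pytest.fixture(scope="session")
def merged_db() -> ScenarioDB:
    return paper_db()


@pytest.fixture()
def small_cohort() -> ScenarioDB:
    return generate_cohort(CohortConfig(n_patients=8, seed=11))


def random_cohort_db(rng: random.Random) -> ScenarioDB:
    """A small random but always-valid database, for round-trip checks."""
    cfg = CohortConfig(
        n_patients=rng.randint(1, 3),
        seed=rng.randrange(2**31),
        mean_diseases=rng.uniform(0, 3),
        mean_injuries=rng.uniform(0, 2),
        mean_surgeries=rng.uniform(0, 2),
        year_range=(1950, 2020),
        p_ineffective=0.3,
        p_negative=0.2,
        p_improvement=0.3,
    )
    return generate_cohort(cfg)
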