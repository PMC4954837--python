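import numpy as np
import pandas as pd
import pytest

from nigra import elo, genotyping, parentage
from nigra.synth import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_groups=1, females_per_group=10, males_per_group=5,
        study_days=240, birth_rate=0.004, seed=1,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_ranks(small_config, small_data):
    pop = small_data.population
    return elo.daily_ranks(
        small_data.agonistic, pop.memberships, pop.roster,
        days=np.arange(small_config.study_days),
    )


@pytest.fixture(scope="session")
def small_genotypes(small_data):
    return genotyping.call_all(small_data.pcr, on_contamination="mark")


@pytest.fixture(scope="session")
def small_paternity(small_data, small_genotypes):
    pop = small_data.population
    return parentage.assign_all(
        small_genotypes, pop.conceptions[["infant", "mother"]]
    )


@pytest.fixture(scope="session")
def infant_table(small_config, small_data, small_ranks, small_paternity):
    from nigra.modeltable import assemble

    pop = small_data.population
    return assemble(
        "infant", small_data.scans, small_data.interactions, small_ranks,
        pop.roster, pop.memberships, pop.conceptions, small_paternity,
        constant_policy="drop",
    )


@pytest.fixture(scope="session")
def male_table(small_config, small_data, small_ranks, small_paternity):
    from nigra.modeltable import assemble

    pop = small_data.population
    return assemble(
        "male", small_data.scans, small_data.interactions, small_ranks,
        pop.roster, pop.memberships, pop.conceptions, small_paternity,
        constant_policy="drop",
    )
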