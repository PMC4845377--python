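from datetime import date

import pytest
from hypothesis import settings

from mdd_comorbidity import SimulationConfig, generate_population, load_catalog

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A 500-patient synthetic cohort reused by the oracle-equivalence tests."""
    cfg = SimulationConfig(n_patients=500, seed=20260923)
    records, truth = generate_population(cfg, catalog)
    return cfg, records, truth
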