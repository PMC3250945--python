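import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cathcea import registry_synth, tables
from cathcea.assemble import build_mortality_library, build_parameter_set
from cathcea.config import default_config
from cathcea.survival_model import LifeTable

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: cohort size for the shared synthetic registry; large enough that the
#: rarest survival cell (ACS female <65 left-main medical) is populated.
N_PATIENTS = 60_000


@pytest.fixture(scope="session")
def tbls():
    return tables.load_tables()


@pytest.fixture(scope="session")
def synth_cfg(tbls):
    return default_config(tbls, seed=1, n_patients=N_PATIENTS)


@pytest.fixture(scope="session")
def patients(synth_cfg):
    return registry_synth.generate_patients(synth_cfg)


@pytest.fixture(scope="session")
def life_table(synth_cfg):
    return LifeTable(registry_synth.generate_life_table(synth_cfg))


@pytest.fixture(scope="session")
def library(patients, life_table):
    return build_mortality_library(patients, life_table)


@pytest.fixture(scope="session")
def base_params(tbls):
    return build_parameter_set(tbls)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
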