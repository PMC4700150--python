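import pytest

from cfams.population_models import make_model
from cfams.simulation_study import StudyConfig, run_study
from cfams.synthetic_data import population_fixture


@pytest.fixture(scope="session")
def specs():
    """The three generating models (multi-factor ones at CO = 0.5)."""
    return {
        "1F": make_model("1F"),
        "2F": make_model("2F", 0.5),
        "3F": make_model("3F", 0.5),
    }


@pytest.fixture(scope="session")
def spec_1f(specs):
    return specs["1F"]


@pytest.fixture(scope="session")
def fixture_1f(spec_1f):
    return population_fixture(spec_1f)


@pytest.fixture(scope="session")
def small_study():
    """A reduced-replication run of the full 156-cell design, shared across
    tests that audit bookkeeping, pairing and rate structure."""
    return run_study(StudyConfig(reps_per_cell=8, master_seed=11))
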