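from pathlib import Path

import pytest

from hapase.pipeline import PipelineConfig, run_pipeline
from hapase.simulate import SimConfig, make_worked_fixture, simulate_cohort

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_dir() -> Path:
    return DATA_DIR / "fixture"


@pytest.fixture(scope="session")
def golden_dir() -> Path:
    return DATA_DIR / "golden"


@pytest.fixture(scope="session")
def worked_cohort():
    return make_worked_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-gene default-shaped cohort shared across module tests."""
    return simulate_cohort(SimConfig(n_genes=60, seed=11))


@pytest.fixture(scope="session")
def small_results(small_cohort):
    return run_pipeline(
        small_cohort.records, small_cohort.tpm, PipelineConfig(seed=11)
    )
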