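import numpy as np
import pytest

from cse_recall.io_cli import load_table1_fixture
from cse_recall.rasch_core import fit_rasch
from cse_recall.synthetic_cohort import CohortSpec, GroupSpec, simulate_cohort


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def explanatory15(table1):
    return table1.explanatory()


@pytest.fixture(scope="session")
def design15(table1):
    return table1.design()


@pytest.fixture(scope="session")
def sim500(table1, design15):
    """One 500-person unidimensional cohort at the reference difficulties."""
    spec = CohortSpec.from_design(
        groups=[GroupSpec("all", 500, -0.6, 1.0)],
        design=design15,
        base_difficulties=table1.delta,
        seed=20240717,
    )
    matrix, truth = simulate_cohort(spec)
    return matrix, truth


@pytest.fixture(scope="session")
def fit500(sim500):
    matrix, _ = sim500
    return fit_rasch(matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
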