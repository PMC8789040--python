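import numpy as np
import pytest

from pdselex.library import load_preset
from pdselex.workflows import run_planted_pair_study


@pytest.fixture(scope="session")
def designs():
    return load_preset()


@pytest.fixture(scope="session")
def rna_design(designs):
    return designs[0]


@pytest.fixture(scope="session")
def protein_design(designs):
    return designs[1]


@pytest.fixture(scope="session")
def planted_study():
    """Full-scale planted-pair campaign plus complete analysis (seeded)."""
    return run_planted_pair_study(seed=1)


@pytest.fixture(scope="session")
def small_study():
    """Reduced planted-pair study for pipeline-structure checks."""
    return run_planted_pair_study(
        seed=3, n_rna=1000, n_protein=20, reads_per_round=20_000,
        focused_library_size=300,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
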