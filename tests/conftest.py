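import pytest

from coroffr import (
    PatientParameters,
    generate_synthetic_tree,
)


@pytest.fixture(scope="session")
def mean_patient() -> PatientParameters:
    """Cohort-mean patient: SBP 128, DBP 85, HR 72, CO 5.26."""
    return PatientParameters(sbp=128.0, dbp=85.0, hr=72.0, co=5.26)


@pytest.fixture(scope="session")
def healthy_tree():
    """Default 7-outlet tree without stenoses."""
    return generate_synthetic_tree(seed=1)


@pytest.fixture(scope="session")
def stenosed_tree():
    """Default tree with a 60% proximal-LAD stenosis."""
    return generate_synthetic_tree(stenosis_spec=[("LAD", 0.60, 0.5)], seed=1)


@pytest.fixture
def single_tube():
    """Smallest tree: aortic stub plus one LAD segment."""
    return generate_synthetic_tree(n_generations=1, seed=7)
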