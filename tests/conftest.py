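import pytest

from sdrase.regions import build_sdr_genes
from sdrase.simulate import TruthConfig, simulate_cohort


@pytest.fixture(scope="session")
def sdr_genes():
    return build_sdr_genes()


@pytest.fixture(scope="session")
def default_dataset():
    """One full study-design cohort, reused read-only across tests."""
    return simulate_cohort(TruthConfig(seed=1))


@pytest.fixture(scope="session")
def sex_of(default_dataset):
    truth = default_dataset.truth.individuals
    return dict(truth[["individual_id", "sex"]].values)
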