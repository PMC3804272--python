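import pytest

from barocomp.io import load_barophily_reference
from barocomp.pipeline import analyze
from barocomp.synthetic import SimConfig, simulate_proteome_pair


@pytest.fixture(scope="session")
def ref():
    return load_barophily_reference()


@pytest.fixture(scope="session")
def small_bundle():
    """A quick synthetic bundle for pipeline-level tests."""
    config = SimConfig(
        n_pairs=60,
        n_unpaired=15,
        n_fsf=30,
        domain_length=(100.0, 20.0, 20),
        intervening_length=(30.0, 10.0, 5),
        seed=7,
    )
    return simulate_proteome_pair(config)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    b = small_bundle
    return analyze(
        b.records_a,
        b.records_b,
        b.assignments_a,
        b.assignments_b,
        b.pairs,
        age_table=b.age_table,
    )
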