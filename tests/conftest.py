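import numpy as np
import pytest

from capricline import MISSING, GenotypeMatrix, SnpRecord


def make_matrix(calls, breed_of=None):
    """GenotypeMatrix from a 2-D array of codes; one breed unless given."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_snp = calls.shape
    breed_of = breed_of or (lambda i: "B1")
    individuals = [(f"ind{i}", breed_of(i)) for i in range(n_ind)]
    snps = [SnpRecord(f"s{j}", "1", j + 1, "A", "B") for j in range(n_snp)]
    return GenotypeMatrix(individuals, snps, calls)


@pytest.fixture
def fixture_tables():
    from capricline import load_fixture_tables

    return load_fixture_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(20240727)
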