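import numpy as np
import pytest

from sweepvolcano.sumstats import HaplotypeMatrix
from sweepvolcano.synthetic_data import toy_fixtures


@pytest.fixture(scope="session")
def toys():
    return toy_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_matrix(rng, n_seq=8, n_sites=12, length=1000) -> HaplotypeMatrix:
    """Random polymorphic matrix (every site segregating)."""
    positions = np.sort(rng.choice(length, size=n_sites, replace=False))
    states = np.zeros((n_seq, n_sites), dtype=np.uint8)
    for j in range(n_sites):
        c = int(rng.integers(1, n_seq))
        carriers = rng.choice(n_seq, size=c, replace=False)
        states[carriers, j] = 1
    return HaplotypeMatrix(positions=positions, states=states, chrom_len=length)
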