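import numpy as np
import pandas as pd
import pytest

from syncerus.containers import GenotypeMatrix, make_site_table


def gm_from_dosage(dosage, pos=None, contig="1", contig_length=10_000_000,
                   samples=None, gq=None):
    """Small GenotypeMatrix straight from a dosage array (rows = samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(m) * 1000 + 100
    sites = make_site_table([contig] * m, pos, ["A"] * m, ["G"] * m)
    return GenotypeMatrix(
        samples=samples or [f"S{i}" for i in range(n)],
        sites=sites,
        dosage=dosage,
        gq=None if gq is None else np.asarray(gq, dtype=np.float32),
        contig_lengths={contig: contig_length},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_symmetric():
    """Factory for random symmetric zero-diagonal matrices."""
    def make(n, seed):
        r = np.random.default_rng(seed)
        a = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        a[iu] = r.random(len(iu[0]))
        return a + a.T
    return make
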