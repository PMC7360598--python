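import numpy as np
import pandas as pd
import pytest

from mvgwas import GenotypeMatrix


def make_genotypes(dosages, chrom=None, pos=None):
    """GenotypeMatrix from a raw dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    variants = pd.DataFrame({
        "chrom": chrom, "variant_id": [f"v{j}" for j in range(m)],
        "pos": pos, "allele1": "A", "allele2": "G"})
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genotypes(rng):
    """60 samples x 8 common variants, no missingness."""
    return make_genotypes(rng.binomial(2, 0.4, size=(60, 8)))
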