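import numpy as np
import pytest
from hypothesis import settings

from ukin import GenotypeMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_genotypes(rng, n, m, missing_rate=0.0, maf_low=0.1,
                     maf_high=0.5) -> GenotypeMatrix:
    """Random HWE genotype matrix with optional missingness."""
    p = rng.uniform(maf_low, maf_high, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    mask = rng.random((n, m)) < missing_rate
    return GenotypeMatrix(dosages, mask,
                          [f"s{i}" for i in range(n)],
                          [f"v{j}" for j in range(m)])


@pytest.fixture
def geno_factory(rng):
    def make(n=6, m=50, missing_rate=0.0, **kw):
        return random_genotypes(rng, n, m, missing_rate, **kw)
    return make
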