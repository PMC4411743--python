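import numpy as np
import pandas as pd
import pytest

from gxekit.containers import GenotypeMatrix


def make_genotypes(dosages, a1="A", a2="G", prefix="S"):
    """GenotypeMatrix from a plain dosage array with generic metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 10,
            "a1": a1,
            "a2": a2,
        }
    )
    samples = pd.DataFrame(
        {"fid": [f"{prefix}{i + 1}" for i in range(n)], "iid": [f"{prefix}{i + 1}" for i in range(n)]}
    )
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_genotypes(rng):
    """60 x 40 matrix with scattered missing calls."""
    d = rng.binomial(2, 0.3, size=(60, 40)).astype(float)
    miss = rng.random(d.shape) < 0.05
    d[miss] = np.nan
    return make_genotypes(d)
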