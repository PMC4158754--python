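import numpy as np
import pytest

from multiblup.genotype_io import GenotypeMatrix, Sample, SnpRecord, normalize
from multiblup.simulate import simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20140901)


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    """3 samples x 2 SNPs with one missing call."""
    samples = [Sample("f1", "i1"), Sample("f2", "i2"), Sample("f3", "i3")]
    snps = [
        SnpRecord("rs1", 1, 1000, "A", "G"),
        SnpRecord("rs2", 1, 2000, "C", "T"),
    ]
    calls = np.array([[0, 2], [1, -1], [2, 1]], dtype=np.int8)
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


@pytest.fixture(scope="session")
def sim_cohort():
    """Small unrelated cohort reused across tests (600 x 500)."""
    g = simulate_genotypes(600, 500, seed=42)
    return g, normalize(g)
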