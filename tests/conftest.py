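import numpy as np
import pytest

from rvlrt.data_io import GenotypeMatrix


def random_genotypes(rng: np.random.Generator, n: int, m: int,
                     p: float = 0.05) -> GenotypeMatrix:
    """Random polymorphic dosage matrix with allele frequency near p."""
    for _ in range(200):
        G = rng.binomial(2, p, (n, m)).astype(float)
        freq = G.mean(axis=0) / 2.0
        if np.all(freq > 0) and np.all(freq < 0.5):
            return GenotypeMatrix(
                samples=[f"s{i}" for i in range(n)],
                variant_ids=[f"v{j}" for j in range(m)],
                counts=G, maf=freq)
    raise RuntimeError("could not draw a polymorphic matrix")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def geno_factory():
    return random_genotypes
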