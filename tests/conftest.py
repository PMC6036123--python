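import numpy as np
import pandas as pd
import pytest

from grammarqtl.data import GenotypeMatrix
from grammarqtl.simulate import SimConfig, simulate_dataset


def small_config(seed: int = 1, **overrides) -> SimConfig:
    base = dict(
        n_snps=600,
        n_chromosomes=4,
        n_per_breed=60,
        heritability=0.3,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest 4-breed panel shared by read-only tests."""
    return simulate_dataset(small_config())


@pytest.fixture()
def tiny_geno():
    """Hand-written 3-sample x 4-SNP matrix for exact-value tests."""
    codes = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 2],
            [2, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    snps = pd.DataFrame(
        {
            "snp": ["s1", "s2", "s3", "s4"],
            "chrom": ["1", "1", "2", "2"],
            "pos": [1000, 2000, 1000, 5000],
            "allele1": ["A", "A", "C", "A"],
            "allele2": ["G", "T", "G", "C"],
        }
    )
    samples = pd.DataFrame(
        {"iid": ["i1", "i2", "i3"], "breed": ["b1", "b1", "b2"], "sex": [1, 0, 1]}
    )
    return GenotypeMatrix(codes, snps, samples)
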