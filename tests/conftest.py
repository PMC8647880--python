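import numpy as np
import pandas as pd
import pytest

from hypwas.geno import GenotypeMatrix
from hypwas.simulate import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_genotypes() -> GenotypeMatrix:
    cfg = SimConfig(n_genotypes=120, n_markers=200, n_chromosomes=4,
                    ld_decay_rho=0.3, seed=11)
    return simulate_genotypes(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_genotype_matrix(dosage, chrom=None, pos=None, sample_ids=None):
    """Hand-build a GenotypeMatrix from a dosage array (samples x markers)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    chrom = chrom if chrom is not None else ["Chr1"] * m
    pos = pos if pos is not None else list(range(1, m + 1))
    markers = pd.DataFrame(
        {
            "marker": [f"{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom,
            "pos": pos,
            "ref": ["A"] * m,
            "alt": ["T"] * m,
        }
    )
    ids = sample_ids or [f"S{i}" for i in range(n)]
    return GenotypeMatrix(ids, markers, dosage)
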