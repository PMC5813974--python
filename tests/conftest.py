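import numpy as np
import pandas as pd
import pytest

from hapeb.genio import PhasedGenotypes


def make_geno(h1, h2, chrom="1", start=100, spacing=100, ids=None):
    """Build a toy PhasedGenotypes from two (n, m) allele matrices."""
    h1 = np.asarray(h1, dtype=np.uint8)
    h2 = np.asarray(h2, dtype=np.uint8)
    n, m = h1.shape
    markers = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": [start + spacing * j for j in range(m)],
            "id": [f"snp{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return PhasedGenotypes(
        individual_ids=ids or [f"s{i}" for i in range(n)],
        markers=markers,
        hap1=h1,
        hap2=h2,
    )


@pytest.fixture(scope="session")
def small_geno():
    """A small simulated population shared across read-only tests."""
    from hapeb.simdata import SimConfig, simulate_genotypes

    cfg = SimConfig(n_individuals=80, n_blocks=12, seed=3)
    return simulate_genotypes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
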