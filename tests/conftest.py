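import numpy as np
import pytest

import sweeppower as sp


@pytest.fixture(scope="session")
def florida():
    """Florida-mouse preset (rounded Table-2 sizes) and the shared region."""
    return sp.preset_model("florida-table2")


@pytest.fixture(scope="session")
def nebraska():
    return sp.preset_model("nebraska-table2")


@pytest.fixture(scope="session")
def small_region():
    """A cheap region for distributional tests."""
    return sp.RegionConfig(L=30_000, n=20, mu=3.7e-8, r=5.6e-7)


@pytest.fixture(scope="session")
def florida_neutral_reps(florida):
    """Shared set of neutral Florida replicates (full region)."""
    model, region = florida
    return [
        sp.simulate_neutral_sample(model, region, ss)
        for ss in sp.replicate_seeds(424_241, 30)
    ]


def random_matrix(rng: np.random.Generator, n: int, S: int, L: float = 1000.0):
    """A random polymorphic haplotype matrix for oracle comparisons."""
    cols = []
    for _ in range(S):
        while True:
            c = rng.integers(0, 2, size=n)
            if 0 < c.sum() < n:
                break
        cols.append(c)
    alleles = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=int)
    positions = np.sort(rng.uniform(0, L, size=S))
    positions += np.arange(S) * 1e-9  # break ties
    return sp.HaplotypeMatrix(alleles.astype(np.uint8), positions, L)
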