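import numpy as np
import pandas as pd
import pytest

from markertrait import SimConfig, simulate_trial
from markertrait.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_trial():
    """Single-species trial, ~250 offspring, 800 loci (shared across tests)."""
    cfg = SimConfig(seed=424, n_species=1, pops_per_species=5,
                    families_per_pop=5, offspring_per_family=10, n_loci=800)
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def multi_trial():
    """Three-species trial at small scale."""
    cfg = SimConfig(seed=87, n_species=3, pops_per_species=3,
                    families_per_pop=3, offspring_per_family=6, n_loci=600)
    return simulate_trial(cfg)


@pytest.fixture
def toy_genotypes():
    """Handwritten 4-sample x 3-locus matrix with metadata and missingness."""
    calls = np.array([[0, 1, 2],
                      [1, np.nan, 2],
                      [2, 0, 2],
                      [0, 0, np.nan]], dtype=float)
    meta = pd.DataFrame({
        "species": ["SY", "SY", "MU", "MU"],
        "population": ["SY_P1", "SY_P1", "MU_P1", "MU_P1"],
        "family": ["F1", "F1", "F2", "F2"],
    }, index=["s1", "s2", "s3", "s4"])
    return GenotypeMatrix(calls, ["s1", "s2", "s3", "s4"],
                          ["L1", "L2", "L3"], meta)
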