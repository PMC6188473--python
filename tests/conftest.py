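import numpy as np
import pandas as pd
import pytest

from crosscell.io import CountMatrix, GeneModel
from crosscell.simulate import (SimulationConfig, simulate_bulk_counts,
                                simulate_gene_models)


@pytest.fixture(scope="session")
def small_models() -> list[GeneModel]:
    return simulate_gene_models(60, seed=42)


@pytest.fixture(scope="session")
def bulk_sim():
    """A small bulk simulation shared by read-only tests."""
    cfg = SimulationConfig(seed=7, n_genes=600, replicates=4)
    return simulate_bulk_counts(cfg)


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    return CountMatrix(np.array([[0, 1], [2, 3], [4, 5]]),
                       ["g1", "g2", "g3"], ["s1", "s2"])


@pytest.fixture()
def plus_gene() -> GeneModel:
    return GeneModel("gp", "chr1", "+", 100, 600,
                     (("gp.t1", 100, 600), ("gp.t2", 150, 400)))


@pytest.fixture()
def minus_gene() -> GeneModel:
    return GeneModel("gm", "chr1", "-", 100, 600, (("gm.t1", 100, 600),))


def two_level_metadata(n_per_group: int, prefix: str = "s") -> pd.DataFrame:
    ids = [f"{prefix}{i}" for i in range(2 * n_per_group)]
    return pd.DataFrame({"sample_id": ids,
                         "grp": ["a"] * n_per_group + ["b"] * n_per_group})
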