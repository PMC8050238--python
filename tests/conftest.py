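import numpy as np
import pandas as pd
import pytest

from stppinet.datatypes import ExpressionMatrix, QueryGeneSet
from stppinet.simulate import SimConfig, simulate_bundle


def small_sim_config(**overrides) -> SimConfig:
    """A reduced simulation grid for fast unit tests."""
    defaults = dict(
        n_genes=80, n_query=5, n_query_nonexpressed=2, n_partners_per_query=3,
        background_edge_prob=0.05, common_cnv_size=6,
        enriched_fraction=1.0, enriched_set_size=20,
        null_set_size=(10, 30), n_null_sets=4,
        seed=7,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_bundle(small_sim_config())


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, hand-written values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 4.0, 8.0],
         [10.0, 10.0, 10.0, 10.0],
         [0.0, 0.0, 0.0, 0.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {"stage": [1, 1, 2, 2], "structure": ["AMY", "AMY", "HIP", "HIP"]},
        index=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, meta)


@pytest.fixture
def query_abc():
    return QueryGeneSet("q", {"QA", "QB"})
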