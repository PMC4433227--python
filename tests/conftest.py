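import numpy as np
import pandas as pd
import pytest

from chickstress import SimConfig, simulate_cohort, simulate_expression_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_birds_per_cell=12, n_genes=400, n_persistent=60)


@pytest.fixture(scope="session")
def cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def expr_study(small_config):
    return simulate_expression_study(small_config)


@pytest.fixture()
def tiny_matrix():
    """Four samples, three genes, with a hand-checkable treatment split."""
    matrix = pd.DataFrame(
        {
            "es1": [2.0, 5.0, 1.0],
            "es2": [4.0, 5.0, 1.0],
            "c1": [1.0, 5.0, 2.0],
            "c2": [3.0, 5.0, 2.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["es1", "es2", "c1", "c2"],
            "age": "young",
            "sex": "M",
            "treatment": ["ES", "ES", "C", "C"],
            "condition": "baseline",
            "pool_members": 1,
        }
    )
    return matrix, meta
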