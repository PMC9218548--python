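import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wingnet.design import default_design
from wingnet.matrix import ExpressionMatrix
from wingnet.simulate import (
    GeneratorConfig,
    generate_truth,
    simulate_counts,
    simulate_junctions,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


SMALL_CONFIG = dict(
    n_genes=150,
    n_mirnas=15,
    n_pairs=10,
    n_events=40,
    utr_length=(120, 200),
    n_eyespot=30,
)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config, seed=0)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    design = default_design()
    genes, mirnas = simulate_counts(small_truth, design)
    events = simulate_junctions(small_truth, design)
    return {"truth": small_truth, "genes": genes, "mirnas": mirnas,
            "events": events, "design": design}


@pytest.fixture()
def meta_4v4():
    """One-stage 4 vs 4 metadata block."""
    return pd.DataFrame(
        {
            "form": ["WS"] * 4 + ["DS"] * 4,
            "stage": ["Wr60"] * 8,
            "replicate": list(range(1, 5)) * 2,
        },
        index=pd.Index([f"s{i}" for i in range(8)], name="sample"),
    )


def nb_counts(rng, mu, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)


@pytest.fixture()
def null_matrix_4v4(meta_4v4):
    """2,000 null NB(mu=100, alpha=0.1) features, 4 vs 4, seed 0."""
    rng = np.random.default_rng(0)
    counts = nb_counts(rng, 100.0, 0.1, (2000, 8))
    return ExpressionMatrix(
        pd.DataFrame(counts, index=[f"f{i:04d}" for i in range(2000)],
                     columns=meta_4v4.index),
        meta_4v4,
    )
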