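import numpy as np
import pandas as pd
import pytest

from sexbias.datatypes import CountMatrix
from sexbias.synth import CohortConfig, generate_bulk


@pytest.fixture(scope="session")
def small_cohort():
    """A compact seeded cohort shared by read-only tests."""
    cfg = CohortConfig(seed=42, n_male_tumor=30, n_female_tumor=30,
                       n_genes=60, n_mirnas=20, n_planted_pairs=5)
    mrna, mirna, samples, truth = generate_bulk(cfg)
    return cfg, mrna, mirna, samples, truth


@pytest.fixture
def tiny_counts():
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(50, size=(12, 8)),
        index=[f"g{i}" for i in range(12)],
        columns=[f"s{i}" for i in range(8)],
    )
    return CountMatrix(counts)


def make_de_table(features_with_lfc, sig=True):
    """Build a minimal DE table: {feature: log2fc}."""
    feats = list(features_with_lfc)
    return pd.DataFrame(
        {
            "log2fc": [features_with_lfc[f] for f in feats],
            "padj": 0.01 if sig else 0.5,
            "significant": sig,
        },
        index=pd.Index(feats, name="feature"),
    )
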