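import numpy as np
import pytest

from ldace import (
    SyntheticConfig,
    build_adjacency,
    build_dataset,
    generate,
    worked_example_fixture,
    sample_negatives,
)
from ldace.ranking import build_similarities


@pytest.fixture(scope="session")
def worked_example():
    """Toy two-disease vocabulary with hand-checkable semantic values."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def small_world():
    """A small planted-cluster world shared across pipeline tests."""
    cfg = SyntheticConfig(
        n_diseases=15, n_lncrnas=25, n_clusters=3,
        within_cluster_prob=0.5, between_cluster_prob=0.05, seed=11,
    )
    vocab, table, clusters = generate(cfg)
    return cfg, vocab, table, clusters


@pytest.fixture(scope="session")
def small_dataset(small_world):
    """Labeled pair set built from the small planted world."""
    _, vocab, table, _ = small_world
    ds, rs = build_similarities(table, vocab)
    adj = build_adjacency(table)
    negatives = sample_negatives(adj, len(table), rng_seed=5)
    return build_dataset(ds, rs, table, negatives)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
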