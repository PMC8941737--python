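"""Synthetic vocabularies and association tables with planted structure.

The generator emulates the guilt-by-association assumption the predictor
relies on — similar lncRNAs partner with similar diseases — by (i)
building a random ontology tree and placing each disease cluster under a
common deep subtree, so within-cluster semantic similarity is high, and
(ii) drawing associations Bernoulli(within) for matched disease/lncRNA
cluster pairs and Bernoulli(between) elsewhere, so interaction profiles
are block-structured.  Everything is driven by a single seed and is
reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationTable, MeshVocabulary


@dataclass
class SyntheticConfig:
    n_diseases: int = 60
    n_lncrnas: int = 120
    n_clusters: int = 4
    tree_depth: int = 3
    branching: int = 3
    within_cluster_prob: float = 0.3
    between_cluster_prob: float = 0.02
    vocab_coverage: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.between_cluster_prob < self.within_cluster_prob <= 1.0:
            raise ValueError("need 0 <= between < within <= 1")
        if not 0.0 <= self.vocab_coverage <= 1.0:
            raise ValueError("vocab_coverage must be in [0, 1]")
        if min(self.n_diseases, self.n_lncrnas, self.n_clusters) < 1:
            raise ValueError("entity and cluster counts must be >= 1")
        if self.tree_depth < 1 or self.branching < 1:
            raise ValueError("tree_depth and branching must be >= 1")


def _ontology_tree(depth: int, branching: int) -> list[str]:
    """Tree numbers of a complete tree: C01..C0b, then dotted children."""
    levels = [[f"C{b + 1:02d}" for b in range(branching)]]
    for _ in range(depth - 1):
        levels.append(
            [f"{tn}.{c + 1:03d}" for tn in levels[-1] for c in range(branching)]
        )
    return [tn for level in levels for tn in level]


def generate(
    config: SyntheticConfig,
) -> tuple[MeshVocabulary, AssociationTable, dict[str, dict[str, int]]]:
    """Generate (vocabulary, association table, ground-truth clusters).

    Cluster anchors sit at the deepest ontology level, which maximizes the
    shared-ancestor overlap of same-cluster diseases.  A fraction
    ``1 - vocab_coverage`` of diseases is left out of the vocabulary so
    the semantic/GIP fallback path of the integration rule is exercised.
    """
    rng = np.random.default_rng(config.seed)
    internal = _ontology_tree(config.tree_depth, config.branching)
    deepest = [tn for tn in internal if tn.count(".") == config.tree_depth - 1]
    anchors = [deepest[c % len(deepest)] for c in range(config.n_clusters)]

    disease_ids = [f"disease_{i:03d}" for i in range(config.n_diseases)]
    lncrna_ids = [f"lnc_{j:03d}" for j in range(config.n_lncrnas)]
    d_cluster = rng.integers(0, config.n_clusters, size=config.n_diseases)
    r_cluster = rng.integers(0, config.n_clusters, size=config.n_lncrnas)

    term_to_treenums: dict[str, set[str]] = {
        f"term_{tn.lower().replace('.', '_')}": {tn} for tn in internal
    }
    covered = rng.random(config.n_diseases) < config.vocab_coverage
    for i, d in enumerate(disease_ids):
        if covered[i]:
            term_to_treenums[d] = {f"{anchors[d_cluster[i]]}.{900 + i:03d}"}
    vocab = MeshVocabulary(term_to_treenums)

    probs = np.where(
        d_cluster[:, None] == r_cluster[None, :],
        config.within_cluster_prob,
        config.between_cluster_prob,
    )
    hits = rng.random((config.n_diseases, config.n_lncrnas)) < probs
    records = [
        (disease_ids[i], lncrna_ids[j]) for i, j in zip(*np.nonzero(hits))
    ]
    if not records:
        raise ValueError("generated association table is empty; raise probabilities")
    table = AssociationTable(records)
    clusters = {
        "diseases": {d: int(c) for d, c in zip(disease_ids, d_cluster)},
        "lncrnas": {r: int(c) for r, c in zip(lncrna_ids, r_cluster)},
    }
    return vocab, table, clusters


def worked_example_fixture() -> tuple[MeshVocabulary, tuple[str, str]]:
    """Tiny worked-example vocabulary for two skin/immune diseases.

    The first disease's ancestor graph has the disease itself, two parents
    and two depth-2 ancestors; the second has two parents, one depth-2 and
    one depth-3 ancestor.  Exactly one node is shared — at depth 2 of the
    first graph and depth 3 of the second — so with decay 0.5 the semantic
    values are 2.5 and 2.375 and their similarity is 0.375/4.875.
    """
    vocab = MeshVocabulary(
        {
            "lupus erythematosus, systemic": {"C17.300.480", "C20.111.590"},
            "connective tissue diseases": {"C17.300"},
            "autoimmune diseases": {"C20.111"},
            "immune system diseases": {"C20"},
            "skin and connective tissue diseases": {"C17"},
            "acne vulgaris": {"C17.800.030.150", "C25.325"},
            "acneiform eruptions": {"C17.800.030"},
            "skin diseases": {"C17.800"},
            "chemically-induced disorders": {"C25"},
        }
    )
    return vocab, ("lupus erythematosus, systemic", "acne vulgaris")
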