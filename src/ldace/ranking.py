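"""Case-study ranking: score every lncRNA for a query disease.

Two designs are supported.  In ``standard`` mode the model trains on all
known positives and the query's known partners are flagged in the output,
so both all-pair and novel-only ranks can be read off.  In
``new_disease`` (cold-start) mode every known pair of the query is
removed before anything is computed: the adjacency matrix, GIP kernels,
negative sample and pair features are all rebuilt from the reduced table,
leaving the query with an all-zero interaction profile so its
representation rests entirely on semantic similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationTable, MeshVocabulary, build_adjacency, sample_negatives
from .semantic import semantic_matrix
from .gip import disease_gip, lncrna_gip, integrate_disease_similarity
from .pair_features import build_dataset, make_pair_vector
from .cnn import train_extractor, extract
from .elm import elm_fit, elm_score
from .evaluation import PipelineSettings
from .matrices import SimilarityMatrix


@dataclass
class RankedList:
    query: str
    mode: str
    entries: list[tuple[str, float, int]]  # (lncrna_id, score, rank)
    known_positives: set[str] = field(default_factory=set)

    def top(self, k: int) -> list[tuple[str, float, int]]:
        return self.entries[:k]

    def rank_of(self, lncrna_id: str) -> int:
        for rid, _, rank in self.entries:
            if rid == lncrna_id:
                return rank
        raise KeyError(f"lncRNA not in ranking: {lncrna_id!r}")


def build_similarities(
    table: AssociationTable,
    vocab: MeshVocabulary,
    delta: float = 0.5,
    alpha_prime: float = 0.5,
    bandwidth_rule: str = "divide",
    diseases: list[str] | None = None,
    lncrnas: list[str] | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Assemble the integrated disease similarity DS and lncRNA similarity RS."""
    adj = build_adjacency(table, diseases=diseases, lncrnas=lncrnas)
    ds1 = semantic_matrix(vocab, adj.diseases, model=1, delta=delta)
    ds2 = semantic_matrix(vocab, adj.diseases, model=2, delta=delta)
    dg = disease_gip(adj, alpha_prime, bandwidth_rule)
    ds = integrate_disease_similarity(ds1, ds2, dg)
    rs = lncrna_gip(adj, alpha_prime, bandwidth_rule)
    return ds, rs


def rank_candidates(
    table: AssociationTable,
    vocab: MeshVocabulary,
    query: str,
    mode: str = "standard",
    settings: PipelineSettings | None = None,
    delta: float = 0.5,
    alpha_prime: float = 0.5,
    seed: int = 42,
) -> RankedList:
    """Train on the chosen design and rank all lncRNAs for the query disease.

    Scores are sorted in non-increasing order, ties broken
    lexicographically by lncRNA id; ranks run 1..n_lncrnas.
    """
    if settings is None:
        settings = PipelineSettings()
    if mode not in ("standard", "new_disease"):
        raise ValueError(f"unknown ranking mode: {mode!r}")
    all_diseases = table.diseases
    all_lncrnas = table.lncrnas
    if query not in all_diseases:
        raise KeyError(f"unknown disease: {query!r}")

    known = {r for d, r in table.records if d == query}
    train_table = table.without_disease(query) if mode == "new_disease" else table

    # keep the query's row (all-zero in cold-start) and the full lncRNA set
    ds, rs = build_similarities(
        train_table, vocab,
        delta=delta, alpha_prime=alpha_prime,
        diseases=all_diseases, lncrnas=all_lncrnas,
    )
    adj = build_adjacency(train_table, diseases=all_diseases, lncrnas=all_lncrnas)
    negatives = sample_negatives(adj, len(train_table), seed)
    dataset = build_dataset(ds, rs, train_table, negatives)

    extractor = train_extractor(dataset, settings.cnn, mode=settings.extractor_mode)
    model = elm_fit(
        extract(extractor, dataset.vectors),
        dataset.labels,
        n_hidden=settings.n_hidden,
        activation=settings.activation,
        seed=settings.seed,
        l2=settings.l2,
    )
    test_vectors = np.stack(
        [make_pair_vector(ds, rs, query, r) for r in all_lncrnas]
    )
    scores = elm_score(model, extract(extractor, test_vectors))

    order = sorted(
        range(len(all_lncrnas)), key=lambda i: (-scores[i], all_lncrnas[i])
    )
    entries = [
        (all_lncrnas[i], float(scores[i]), rank)
        for rank, i in enumerate(order, start=1)
    ]
    return RankedList(query, mode, entries, known_positives=known)
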