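"""MeSH-hierarchy semantic similarity between diseases.

Every disease is expanded into the directed acyclic graph (DAG) of itself
and all its hierarchy ancestors, found by prefix-truncating its tree
numbers.  Two contribution schemes weight each DAG node:

* model 1 (decay): the disease contributes 1 to itself and each ancestor
  contributes ``max(delta * contribution of its DAG children)``, so weight
  decays geometrically with distance from the disease;
* model 2 (information content): a node contributes
  ``-ln(n_DAGs_containing_it / n_diseases)``, so ubiquitous ancestors
  contribute little and rare ones a lot.

The similarity of two diseases is the summed contribution of their shared
DAG nodes (counted from both sides) over the sum of their total semantic
values — a Jaccard-flavoured overlap score in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_io import MeshVocabulary
from .matrices import SimilarityMatrix


@dataclass
class DiseaseDAG:
    """A disease term with its in-vocabulary ancestor graph.

    ``edges`` are (child, parent) pairs following the hierarchy upward;
    ``depth_map`` holds the minimal number of parent hops from the root
    disease to each node.
    """

    root: str
    nodes: set[str]
    edges: set[tuple[str, str]]
    depth_map: dict[str, int]

    def children_of(self, term: str) -> list[str]:
        return [c for c, p in self.edges if p == term]


@dataclass
class ContributionMap:
    """Per-node semantic contributions and their total for one disease DAG."""

    model: int
    root: str
    values: dict[str, float]
    semantic_value: float


def _strict_prefixes(treenum: str) -> list[str]:
    """All strict segment-wise prefixes of a tree number, longest first."""
    segs = treenum.split(".")
    return [".".join(segs[:k]) for k in range(len(segs) - 1, 0, -1)]


def build_dag(term: str, vocab: MeshVocabulary) -> DiseaseDAG:
    """Expand a disease into its DAG of in-vocabulary hierarchy ancestors.

    A vocabulary term belongs to the DAG when one of its tree numbers is a
    strict prefix of one of the root term's tree numbers.  Each node is
    linked to the term owning the nearest present prefix of the relevant
    tree number, so the graph stays connected even if an intermediate
    hierarchy level has no vocabulary entry.
    """
    if term not in vocab:
        raise KeyError(f"term not in vocabulary: {term!r}")

    # tree numbers relevant to this DAG, with the term owning each
    relevant: dict[str, str] = {}  # treenum -> owning term
    for tn in vocab.term_to_treenums[term]:
        relevant[tn] = term
        for pfx in _strict_prefixes(tn):
            owner = vocab.treenum_to_term.get(pfx)
            if owner is not None and owner != term:
                relevant.setdefault(pfx, owner)

    nodes = set(relevant.values())
    edges: set[tuple[str, str]] = set()
    for tn, owner in relevant.items():
        for pfx in _strict_prefixes(tn):
            parent = relevant.get(pfx)
            if parent is not None:
                if parent != owner:
                    edges.add((owner, parent))
                break  # only the nearest present ancestor

    # minimal hop distance from the root following child->parent edges
    depth_map = {term: 0}
    frontier = [term]
    while frontier:
        nxt = []
        for u in frontier:
            for c, p in edges:
                if c == u and p not in depth_map:
                    depth_map[p] = depth_map[u] + 1
                    nxt.append(p)
        frontier = nxt
    return DiseaseDAG(root=term, nodes=nodes, edges=edges, depth_map=depth_map)


def contributions_model1(dag: DiseaseDAG, delta: float = 0.5) -> ContributionMap:
    """Decay-based contributions: 1 at the root, times delta per hierarchy step.

    Each ancestor takes ``max(delta * contribution)`` over its DAG children,
    so a node reachable along several paths keeps the weight of the
    shortest one.
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    values: dict[str, float] = {}

    def contrib(t: str) -> float:
        if t in values:
            return values[t]
        if t == dag.root:
            values[t] = 1.0
        else:
            children = dag.children_of(t)
            values[t] = max(delta * contrib(c) for c in children)
        return values[t]

    for t in dag.nodes:
        contrib(t)
    return ContributionMap(1, dag.root, values, sum(values.values()))


def contributions_model2(
    dag: DiseaseDAG, dag_membership_counts: dict[str, int], n_diseases: int
) -> ContributionMap:
    """Information-content contributions: -ln(fraction of disease DAGs holding t)."""
    values: dict[str, float] = {}
    for t in dag.nodes:
        count = dag_membership_counts.get(t, 0)
        if count < 1:
            raise ValueError(f"node {t!r} has membership count 0")
        if count > n_diseases:
            raise ValueError(f"membership count of {t!r} exceeds n_diseases")
        values[t] = -math.log(count / n_diseases)
    return ContributionMap(2, dag.root, values, sum(values.values()))


def semantic_similarity(i: ContributionMap, j: ContributionMap) -> float:
    """Shared-ancestor contribution overlap, symmetric, in [0, 1]."""
    if i.model != j.model:
        raise ValueError("cannot compare contribution maps of different models")
    shared = i.values.keys() & j.values.keys()
    numer = sum(i.values[t] + j.values[t] for t in shared)
    denom = i.semantic_value + j.semantic_value
    if denom == 0.0:
        # degenerate model-2 case: every node appears in every DAG
        return 1.0 if i.values.keys() == j.values.keys() else 0.0
    return numer / denom


def semantic_matrix(
    vocab: MeshVocabulary,
    diseases: list[str],
    model: int = 1,
    delta: float = 0.5,
) -> SimilarityMatrix:
    """Pairwise semantic similarity over an ordered disease list.

    Diseases absent from the vocabulary get placeholder zero rows and are
    unflagged in ``defined_mask``; the integration step substitutes the
    GIP kernel value for those.  Model-2 membership counts are taken over
    the diseases of this list that have vocabulary entries, not over the
    whole vocabulary.
    """
    if model not in (1, 2):
        raise ValueError(f"model must be 1 or 2, got {model}")
    defined = np.array([d in vocab for d in diseases], dtype=bool)
    dags = {d: build_dag(d, vocab) for d, ok in zip(diseases, defined) if ok}

    if model == 1:
        cmaps = {d: contributions_model1(g, delta) for d, g in dags.items()}
    else:
        counts: dict[str, int] = {}
        for g in dags.values():
            for t in g.nodes:
                counts[t] = counts.get(t, 0) + 1
        n_def = len(dags)
        cmaps = {
            d: contributions_model2(g, counts, n_def) for d, g in dags.items()
        }

    n = len(diseases)
    values = np.zeros((n, n))
    for a, da in enumerate(diseases):
        if not defined[a]:
            continue
        values[a, a] = 1.0
        for b in range(a + 1, n):
            db = diseases[b]
            if not defined[b]:
                continue
            s = semantic_similarity(cmaps[da], cmaps[db])
            values[a, b] = values[b, a] = s
    return SimilarityMatrix(values, list(diseases), defined_mask=defined)
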