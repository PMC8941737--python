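import math

import numpy as np
import pytest

from ldace import (
    build_dag,
    contributions_model1,
    contributions_model2,
    semantic_matrix,
    semantic_similarity,
)
from ldace.data_io import MeshVocabulary


@pytest.fixture()
def chain_vocab():
    # three terms on a single hierarchy path
    return MeshVocabulary(
        {
            "leaf": {"C17.300.480"},
            "mid": {"C17.300"},
            "top": {"C17"},
        }
    )


class TestBuildDag:
    def test_prefix_enumeration_oracle(self, chain_vocab):
        # brute force: every vocab term owning a strict prefix of the leaf's
        # tree number must be a node, and nothing else
        dag = build_dag("leaf", chain_vocab)
        expected = {"leaf"}
        for term, tns in chain_vocab.term_to_treenums.items():
            for tn in tns:
                if "C17.300.480".startswith(tn + "."):
                    expected.add(term)
        assert dag.nodes == expected
        assert len(dag.edges) == 2

    def test_singleton_dag(self):
        vocab = MeshVocabulary({"orphan": {"Z99.123"}})
        dag = build_dag("orphan", vocab)
        assert dag.nodes == {"orphan"}
        assert dag.edges == set()

    def test_toy_dag_sizes(self, worked_example):
        vocab, (lupus, acne) = worked_example
        assert len(build_dag(lupus, vocab).nodes) == 5
        assert len(build_dag(acne, vocab).nodes) == 5

    def test_toy_shared_node_depths(self, worked_example):
        vocab, (lupus, acne) = worked_example
        g1, g2 = build_dag(lupus, vocab), build_dag(acne, vocab)
        shared = g1.nodes & g2.nodes
        assert len(shared) == 1
        (t,) = shared
        assert g1.depth_map[t] == 2
        assert g2.depth_map[t] == 3

    def test_missing_intermediate_level_stays_connected(self):
        # "mid" has no vocabulary entry: leaf links straight to top
        vocab = MeshVocabulary({"leaf": {"C17.300.480"}, "top": {"C17"}})
        dag = build_dag("leaf", vocab)
        assert dag.nodes == {"leaf", "top"}
        assert dag.edges == {("leaf", "top")}
        assert dag.depth_map["top"] == 1

    def test_unknown_term(self, chain_vocab):
        with pytest.raises(KeyError):
            build_dag("nonexistent", chain_vocab)


class TestModel1:
    def test_chain_contributions(self, chain_vocab):
        cm = contributions_model1(build_dag("leaf", chain_vocab), delta=0.5)
        assert cm.values == {"leaf": 1.0, "mid": 0.5, "top": 0.25}
        assert cm.semantic_value == 1.75

    def test_toy_semantic_values(self, worked_example):
        vocab, (lupus, acne) = worked_example
        assert contributions_model1(build_dag(lupus, vocab)).semantic_value == 2.5
        assert contributions_model1(build_dag(acne, vocab)).semantic_value == 2.375

    def test_singleton_semantic_value(self):
        vocab = MeshVocabulary({"orphan": {"Z99"}})
        assert contributions_model1(build_dag("orphan", vocab)).semantic_value == 1.0

    def test_depth_decay_bound(self, worked_example):
        # a node at minimal depth k contributes at least delta**k
        vocab, (lupus, _) = worked_example
        dag = build_dag(lupus, vocab)
        cm = contributions_model1(dag, delta=0.5)
        for t, depth in dag.depth_map.items():
            assert cm.values[t] >= 0.5**depth - 1e-15

    @pytest.mark.parametrize("delta", [0.0, -0.5, 1.5])
    def test_invalid_delta(self, chain_vocab, delta):
        dag = build_dag("leaf", chain_vocab)
        with pytest.raises(ValueError):
            contributions_model1(dag, delta=delta)


class TestModel2:
    def test_hand_values(self, chain_vocab):
        dag = build_dag("leaf", chain_vocab)
        counts = {"leaf": 1, "mid": 2, "top": 4}
        cm = contributions_model2(dag, counts, n_diseases=4)
        assert cm.values["mid"] == pytest.approx(-math.log(0.5), abs=1e-12)
        assert cm.values["top"] == 0.0  # appears in every DAG
        # semantic value is the plain sum of node contributions
        assert cm.semantic_value == pytest.approx(sum(cm.values.values()))

    def test_zero_count_rejected(self, chain_vocab):
        dag = build_dag("leaf", chain_vocab)
        with pytest.raises(ValueError):
            contributions_model2(dag, {"leaf": 1, "mid": 0, "top": 1}, 4)


class TestSemanticSimilarity:
    def test_toy_pair_value(self, worked_example):
        vocab, (lupus, acne) = worked_example
        c1 = contributions_model1(build_dag(lupus, vocab))
        c2 = contributions_model1(build_dag(acne, vocab))
        sim = semantic_similarity(c1, c2)
        assert sim == pytest.approx(0.375 / 4.875, abs=1e-15)
        assert round(sim, 4) == 0.0769

    def test_self_similarity_is_one(self, worked_example):
        vocab, (lupus, _) = worked_example
        cm = contributions_model1(build_dag(lupus, vocab))
        assert semantic_similarity(cm, cm) == pytest.approx(1.0, abs=1e-15)

    def test_model2_self_similarity_is_one(self, worked_example):
        vocab, (lupus, acne) = worked_example
        g1, g2 = build_dag(lupus, vocab), build_dag(acne, vocab)
        counts = {}
        for g in (g1, g2):
            for t in g.nodes:
                counts[t] = counts.get(t, 0) + 1
        cm = contributions_model2(g1, counts, 2)
        assert semantic_similarity(cm, cm) == pytest.approx(1.0)

    def test_disjoint_dags(self):
        vocab = MeshVocabulary({"a": {"C01.100"}, "b": {"F03.200"}})
        ca = contributions_model1(build_dag("a", vocab))
        cb = contributions_model1(build_dag("b", vocab))
        assert semantic_similarity(ca, cb) == 0.0

    def test_model_mismatch(self, chain_vocab):
        dag = build_dag("leaf", chain_vocab)
        c1 = contributions_model1(dag)
        c2 = contributions_model2(dag, {t: 1 for t in dag.nodes}, 3)
        with pytest.raises(ValueError):
            semantic_similarity(c1, c2)


class TestSemanticMatrix:
    def test_toy_two_by_two(self, worked_example):
        vocab, (lupus, acne) = worked_example
        mat = semantic_matrix(vocab, [lupus, acne], model=1)
        expected = 0.375 / 4.875
        assert np.allclose(
            mat.values, [[1.0, expected], [expected, 1.0]], atol=1e-15
        )

    def test_missing_disease_masked(self, worked_example):
        vocab, (lupus, _) = worked_example
        mat = semantic_matrix(vocab, [lupus, "not a term"], model=1)
        assert mat.defined_mask.tolist() == [True, False]
        assert mat.values[1].sum() == 0.0

    @pytest.mark.parametrize("model", [1, 2])
    def test_matches_pairwise_recomputation(self, worked_example, model):
        vocab, _ = worked_example
        diseases = sorted(vocab.term_to_treenums)
        mat = semantic_matrix(vocab, diseases, model=model)
        dags = {d: build_dag(d, vocab) for d in diseases}
        if model == 1:
            cmaps = {d: contributions_model1(g) for d, g in dags.items()}
        else:
            counts: dict[str, int] = {}
            for g in dags.values():
                for t in g.nodes:
                    counts[t] = counts.get(t, 0) + 1
            cmaps = {
                d: contributions_model2(g, counts, len(dags))
                for d, g in dags.items()
            }
        for i, di in enumerate(diseases):
            for j, dj in enumerate(diseases):
                expected = (
                    1.0 if i == j
                    else semantic_similarity(cmaps[di], cmaps[dj])
                )
                assert mat.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_in_unit_interval(self, small_world):
        _, vocab, table, _ = small_world
        mat = semantic_matrix(vocab, table.diseases, model=1)
        assert np.allclose(mat.values, mat.values.T)
        assert mat.values.min() >= 0.0 and mat.values.max() <= 1.0
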