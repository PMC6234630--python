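"""Weisfeiler-Lehman kernel against a brute-force subtree oracle, plus the
data-driven class-vector similarities and minimum-distance prediction."""

import math

import networkx as nx
import numpy as np
import pytest

from headachedx import (
    ClassVector,
    SimilarityBlock,
    WFConfig,
    build_class_vectors,
    cosine_similarity,
    nearest_class_predict,
    rbf_similarity,
    vector_similarity_block,
    wf_kernel,
    wf_similarity_block,
)
from headachedx.kb import KnowledgeGraph

from oracles import brute_force_wl_kernel, knowledge_graph_to_nx


def random_graph(rng: np.random.Generator, max_nodes=12, n_labels=4):
    """Random rooted directed multigraph with small label alphabets."""
    n = int(rng.integers(2, max_nodes + 1))
    g = nx.MultiDiGraph(root=0)
    for v in range(n):
        g.add_node(v, label=f"L{rng.integers(n_labels)}")
    m = int(rng.integers(1, 2 * n + 1))
    for _ in range(m):
        u, v = rng.integers(n, size=2)
        g.add_edge(int(u), int(v), label=f"p{rng.integers(n_labels)}")
    # make sure the root reaches something
    g.add_edge(0, int(rng.integers(n)), label=f"p{rng.integers(n_labels)}")
    return g


class TestWLKernel:
    def test_matches_brute_force_subtree_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        graphs = [random_graph(rng) for _ in range(60)]
        for i in range(0, 60, 2):
            g1, g2 = graphs[i], graphs[i + 1]
            d = int(rng.integers(1, 4))
            h = int(rng.integers(0, 4))
            cfg = WFConfig(d=d, h=h, normalize=False)
            expected = brute_force_wl_kernel(g1, g2, d, h)
            assert wf_kernel(g1, g2, cfg) == expected
            assert wf_kernel(g2, g1, cfg) == expected  # symmetry

    def test_normalized_self_similarity_is_one(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = random_graph(rng)
            assert wf_kernel(g, g, WFConfig(normalize=True)) == pytest.approx(1.0)

    def test_disjoint_label_sets_score_zero(self):
        g1 = KnowledgeGraph(frozenset({("r", "has-a", "x")}), "r")
        g2 = KnowledgeGraph(frozenset({("r", "has-b", "y")}), "r")
        # roots share their canonical label, so strip them apart via nx
        n1, n2 = knowledge_graph_to_nx(g1), knowledge_graph_to_nx(g2)
        n1.nodes["r"]["label"] = "rootA"
        n2.nodes["r"]["label"] = "rootB"
        assert wf_kernel(n1, n2, WFConfig(normalize=True)) == 0.0

    def test_shared_triple_toy_graphs_match_oracle(self):
        g1 = KnowledgeGraph(
            frozenset({("r", "has-a", "x"), ("r", "has-b", "y"), ("r", "has-c", "z")}),
            "r",
        )
        g2 = KnowledgeGraph(
            frozenset({("r", "has-a", "x"), ("r", "has-b", "q"), ("r", "has-d", "w")}),
            "r",
        )
        cfg = WFConfig(d=2, h=2, normalize=False)
        expected = brute_force_wl_kernel(
            knowledge_graph_to_nx(g1), knowledge_graph_to_nx(g2), 2, 2
        )
        assert expected > 0
        assert wf_kernel(g1, g2, cfg) == expected

    def test_h_zero_is_dot_product_of_raw_label_counts(self):
        g1 = KnowledgeGraph(
            frozenset({("r", "has-a", "x"), ("r", "has-a", "y")}), "r"
        )
        g2 = KnowledgeGraph(
            frozenset({("r", "has-a", "x"), ("r", "has-b", "x")}), "r"
        )
        # shared labels: root node (1*1), node x (1*1), edge has-a (2*1)
        assert wf_kernel(g1, g2, WFConfig(d=2, h=0, normalize=False)) == 4.0

    def test_empty_graph_scores_zero_with_warning(self, caplog):
        empty = KnowledgeGraph(frozenset(), "r")
        other = KnowledgeGraph(frozenset({("r", "has-a", "x")}), "r")
        with caplog.at_level("WARNING"):
            assert wf_kernel(empty, other) == 0.0
        assert "empty graph" in caplog.text

    def test_small_gram_matrices_are_positive_semidefinite(self):
        rng = np.random.default_rng(5)
        graphs = [random_graph(rng, max_nodes=8) for _ in range(6)]
        cfg = WFConfig(d=2, h=2, normalize=True)
        K = np.array([[wf_kernel(a, b, cfg) for b in graphs] for a in graphs])
        assert np.min(np.linalg.eigvalsh((K + K.T) / 2)) >= -1e-8


class TestConceptSimilarities:
    def test_noise_free_samples_are_closest_to_their_own_concept(
        self, kb, noise_free_cohort
    ):
        block = wf_similarity_block(noise_free_cohort, kb)
        assert block.matrix.shape == (noise_free_cohort.n, kb.C)
        assert np.all((block.matrix >= 0) & (block.matrix <= 1))
        predicted = nearest_class_predict(block)
        assert predicted == noise_free_cohort.labels

    def test_typing_triples_do_not_influence_the_block(self, kb, noise_free_cohort):
        from headachedx import encode_sample, strip_typing
        from headachedx.kb import concept_graph
        from headachedx.kernels import class_similarity_features

        small = noise_free_cohort.subset(range(20))
        graphs = [
            encode_sample(fv, kb, f"sample-{i}")
            for i, fv in enumerate(small.iter_samples())
        ]
        cgraphs = [concept_graph(kb, c) for c in kb.class_labels]
        with_labels = class_similarity_features(graphs, cgraphs, kb.class_labels)
        pre_stripped = class_similarity_features(
            [strip_typing(g) for g in graphs], cgraphs, kb.class_labels
        )
        np.testing.assert_array_equal(with_labels.matrix, pre_stripped.matrix)


class TestClassVectors:
    def test_singleton_class_is_its_own_centroid_and_medoid(self, kb,
                                                            noise_free_cohort):
        one_each = noise_free_cohort.subset(
            [noise_free_cohort.labels.index(c) for c in noise_free_cohort.classes]
        )
        for mode in ("centroid", "medoid"):
            vectors = build_class_vectors(one_each, mode)
            from headachedx._encoding import NumericEncoder

            X = NumericEncoder(one_each.vocab).transform(one_each.frame)
            for i, cv in enumerate(vectors):
                np.testing.assert_array_equal(cv.vector, X[i])

    def test_centroid_is_the_mean_indicator(self):
        import pandas as pd

        from headachedx import LabeledDataset
        from headachedx.kb import AttributeSpec

        vocab = (AttributeSpec("f", "binary", ("false", "true")),)
        frame = pd.DataFrame(
            {"f": ["true", "true", "true", "false"], "label": ["a"] * 4}
        )
        ds = LabeledDataset(frame, vocab, ["a"])
        assert build_class_vectors(ds, "centroid")[0].vector[0] == 0.75

    def test_medoid_minimises_summed_distance(self):
        import pandas as pd

        from headachedx import LabeledDataset
        from headachedx.kb import AttributeSpec

        domain = tuple(f"v{i}" for i in range(11))
        vocab = (AttributeSpec("x", "ordinal-categorical", domain),)
        frame = pd.DataFrame({"x": ["v0", "v0", "v10"], "label": ["a"] * 3})
        ds = LabeledDataset(frame, vocab, ["a"])
        assert build_class_vectors(ds, "medoid")[0].vector[0] == 0.0


class TestVectorSimilarities:
    def test_identity_scores_one(self):
        c = ClassVector("a", np.array([1.0, 0.0, 2.0]), "centroid")
        assert rbf_similarity(c.vector, c, gamma=0.3) == pytest.approx(1.0)
        assert cosine_similarity(c.vector, c) == pytest.approx(1.0)

    def test_rbf_closed_form_on_four_flipped_bits(self):
        x = np.zeros(10)
        c = np.zeros(10)
        c[:4] = 1.0
        assert rbf_similarity(x, ClassVector("a", c, "centroid"), 0.25) == (
            pytest.approx(math.exp(-1.0))
        )

    def test_rbf_tends_to_one_as_gamma_vanishes(self):
        x, c = np.zeros(3), np.ones(3) * 5
        assert rbf_similarity(x, ClassVector("a", c, "centroid"), 1e-12) == (
            pytest.approx(1.0, abs=1e-9)
        )

    def test_zero_norm_cosine_is_zero(self):
        assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            rbf_similarity(np.zeros(3), np.zeros(4), 1.0)

    def test_block_rows_in_unit_interval_and_rbf_separates_noise_free(
        self, kb, noise_free_cohort
    ):
        block = vector_similarity_block(noise_free_cohort, "rbf")
        assert np.all((block.matrix >= 0) & (block.matrix <= 1))
        assert nearest_class_predict(block) == noise_free_cohort.labels


class TestNearestClass:
    def test_argmax_and_canonical_tie_break(self):
        block = SimilarityBlock(
            np.array([[0.9, 0.2, 0.1], [0.5, 0.5, 0.1]]), "wf", ["a", "b", "c"]
        )
        assert nearest_class_predict(block) == ["a", "a"]

    def test_all_zero_row_warns_and_uses_first_class(self, caplog):
        block = SimilarityBlock(np.zeros((1, 2)), "wf", ["a", "b"])
        with caplog.at_level("WARNING"):
            assert nearest_class_predict(block) == ["a"]
        assert "all-zero" in caplog.text
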