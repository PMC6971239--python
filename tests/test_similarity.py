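import numpy as np
import pytest

from ontosample.annotator import SemanticSet
from ontosample.ontology import (
    Concept, OntologyGraph, convert_part_of, information_content, parse_obo,
)
from ontosample.similarity import (
    CollapseConfig, SampleSimilarityMatrix, SimilarityConfig, collapse,
    combine_ontologies, groupwise_similarity, pairwise_similarity,
    sample_similarity_matrix,
)
from ontosample.fixtures import make_toy_ontology

from _oracles import (
    brute_force_jiang, brute_force_lin, brute_force_mica_ic, random_dag,
)

LIN_T3_T4 = 1 - np.log(3) / np.log(5)  # = IC(T:1), their only informative ancestor


def _graph_from(nodes, edges):
    return OntologyGraph({n: Concept(n, name=n) for n in nodes},
                         {(c, p, "is_a") for c, p in edges})


class TestPairwise:
    def test_lin_identity(self, tissue_graph, tissue_ic):
        assert pairwise_similarity(tissue_graph, tissue_ic, "T:3", "T:3") == 1.0

    def test_lin_toy_value(self, tissue_graph, tissue_ic):
        got = pairwise_similarity(tissue_graph, tissue_ic, "T:3", "T:4", "lin")
        assert got == pytest.approx(LIN_T3_T4, abs=1e-12)

    def test_resnik_against_root_is_zero(self, tissue_graph, tissue_ic):
        for cid in ["T:1", "T:2", "T:3", "T:4"]:
            assert pairwise_similarity(tissue_graph, tissue_ic, cid, "T:0",
                                       "resnik") == 0.0

    def test_jiang_toy_value(self, tissue_graph, tissue_ic):
        got = pairwise_similarity(tissue_graph, tissue_ic, "T:3", "T:4",
                                  "jiang_conrath")
        assert got == pytest.approx(1 / (1 + 2 - 2 * LIN_T3_T4), abs=1e-12)

    def test_edge_rada_toy_value(self, tissue_graph, tissue_ic):
        # shortest path T:3 -> T:1 -> T:4 has two edges
        got = pairwise_similarity(tissue_graph, tissue_ic, "T:3", "T:4",
                                  "edge_rada")
        assert got == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_common_ancestor_enumeration_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(8):
            nodes, edges = random_dag(rng, int(rng.integers(10, 120)))
            g = _graph_from(nodes, edges)
            ic = information_content(g, "seco")
            for _ in range(30):
                c1, c2 = rng.choice(nodes, 2, replace=True)
                mica_ic = brute_force_mica_ic(edges, ic.values, c1, c2)
                resnik = pairwise_similarity(g, ic, c1, c2, "resnik")
                assert resnik == pytest.approx(mica_ic if mica_ic is not None else 0.0,
                                               abs=1e-9)
                assert pairwise_similarity(g, ic, c1, c2, "lin") == pytest.approx(
                    brute_force_lin(edges, ic.values, c1, c2), abs=1e-9)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        nodes, edges = random_dag(rng, 60)
        g = _graph_from(nodes, edges)
        ic = information_content(g)
        for _ in range(40):
            c1, c2 = rng.choice(nodes, 2, replace=True)
            for measure in ("resnik", "lin", "jiang_conrath", "edge_rada"):
                a = pairwise_similarity(g, ic, c1, c2, measure)
                b = pairwise_similarity(g, ic, c2, c1, measure)
                assert a == pytest.approx(b, abs=1e-12)
                if measure != "resnik":
                    assert -1e-12 <= a <= 1 + 1e-12

    def test_disconnected_concepts_score_zero(self):
        g = _graph_from(["A", "B"], set())
        ic = information_content(g)
        assert pairwise_similarity(g, ic, "A", "B") == 0.0

    def test_obsolete_concept_rejected(self, tmp_path):
        obo = tmp_path / "o.obo"
        obo.write_text("[Term]\nid: X:0\nname: r\n\n"
                       "[Term]\nid: X:1\nname: gone\nis_obsolete: true\n")
        g = parse_obo(obo)
        ic = information_content(g)
        with pytest.raises(ValueError):
            pairwise_similarity(g, ic, "X:1", "X:0")


class TestGroupwise:
    def test_identical_singletons(self, tissue_graph, tissue_ic):
        assert groupwise_similarity(tissue_graph, tissue_ic,
                                    {"T:3"}, {"T:3"}) == 1.0

    def test_bma_hand_value(self, tissue_graph, tissue_ic):
        # ½[(1 + LIN(T:4,T:3))/2 + max(1, LIN) ] with LIN(T:3,T:4)=IC(T:1)
        expected = ((1 + LIN_T3_T4) / 2 + 1) / 2
        got = groupwise_similarity(tissue_graph, tissue_ic,
                                   {"T:3", "T:4"}, {"T:3"})
        assert got == pytest.approx(expected, abs=1e-12)

    def test_bma_symmetric(self, tissue_graph, tissue_ic):
        rng = np.random.default_rng(3)
        concepts = ["T:0", "T:1", "T:2", "T:3", "T:4"]
        for _ in range(20):
            a = set(rng.choice(concepts, rng.integers(1, 4), replace=False))
            b = set(rng.choice(concepts, rng.integers(1, 4), replace=False))
            x = groupwise_similarity(tissue_graph, tissue_ic, a, b)
            y = groupwise_similarity(tissue_graph, tissue_ic, b, a)
            assert x == pytest.approx(y, abs=1e-12)

    def test_empty_set_rejected(self, tissue_graph, tissue_ic):
        with pytest.raises(ValueError):
            groupwise_similarity(tissue_graph, tissue_ic, set(), {"T:3"})

    @pytest.mark.parametrize("strategy,expected", [
        ("max", 1.0),
        ("min", LIN_T3_T4),
        ("average", (1 + LIN_T3_T4) / 2),
    ])
    def test_other_strategies(self, tissue_graph, tissue_ic, strategy, expected):
        got = groupwise_similarity(tissue_graph, tissue_ic,
                                   {"T:3", "T:4"}, {"T:3"}, strategy=strategy)
        assert got == pytest.approx(expected, abs=1e-12)


def _singleton_sets(*cids):
    return [SemanticSet([f"s{i}"], frozenset([c])) for i, c in enumerate(cids)]


class TestSampleMatrix:
    def test_three_singletons(self, tissue_graph, tissue_ic):
        m = sample_similarity_matrix(_singleton_sets("T:3", "T:4", "T:2"),
                                     tissue_graph,
                                     SimilarityConfig(ic=tissue_ic))
        assert m.values.shape == (3, 3)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values, m.values.T)
        assert m.values[0, 1] == pytest.approx(LIN_T3_T4)

    def test_identical_sets_all_ones(self, tissue_graph, tissue_ic):
        m = sample_similarity_matrix(_singleton_sets("T:3", "T:3", "T:3"),
                                     tissue_graph, SimilarityConfig(ic=tissue_ic))
        assert np.allclose(m.values, 1.0)

    def test_permutation_consistency(self, tissue_graph, tissue_ic):
        sets = _singleton_sets("T:3", "T:4", "T:2")
        m1 = sample_similarity_matrix(sets, tissue_graph,
                                      SimilarityConfig(ic=tissue_ic))
        m2 = sample_similarity_matrix(sets[::-1], tissue_graph,
                                      SimilarityConfig(ic=tissue_ic))
        assert np.allclose(m1.values, m2.values[::-1, ::-1])

    def test_unknown_concept_listed(self, tissue_graph, tissue_ic):
        sets = _singleton_sets("T:3", "Z:9")
        with pytest.raises(KeyError, match="Z:9"):
            sample_similarity_matrix(sets, tissue_graph,
                                     SimilarityConfig(ic=tissue_ic))


class TestCombine:
    def test_mean_of_duplicates_is_identity(self, tissue_graph, tissue_ic):
        m = sample_similarity_matrix(_singleton_sets("T:3", "T:4"), tissue_graph,
                                     SimilarityConfig(ic=tissue_ic))
        combined = combine_ontologies([m, m])
        assert np.allclose(combined.values, m.values)

    def test_mean_of_ones_and_zeros(self):
        ids = ["a", "b"]
        ones = SampleSimilarityMatrix(ids, np.ones((2, 2)))
        zeros = SampleSimilarityMatrix(ids, np.zeros((2, 2)))
        assert np.allclose(combine_ontologies([ones, zeros]).values, 0.5)

    def test_median_matches_elementwise_oracle(self):
        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(4)]
        mats = []
        for _ in range(3):
            v = rng.random((4, 4))
            v = (v + v.T) / 2
            mats.append(SampleSimilarityMatrix(ids, v))
        combined = combine_ontologies(mats, aggregator=np.median)
        expected = np.median(np.stack([m.values for m in mats]), axis=0)
        assert np.allclose(combined.values, expected)

    def test_id_mismatch_rejected(self):
        m1 = SampleSimilarityMatrix(["a", "b"], np.eye(2))
        m2 = SampleSimilarityMatrix(["a", "c"], np.eye(2))
        with pytest.raises(ValueError):
            combine_ontologies([m1, m2])


class TestCollapse:
    def test_identical_sets_merge_at_any_threshold(self, tissue_graph, tissue_ic):
        sets = _singleton_sets("T:3", "T:3")
        m = sample_similarity_matrix(sets, tissue_graph, SimilarityConfig(ic=tissue_ic))
        for tau in (0.0, 0.5, 1.0):
            merged = collapse(sets, m, CollapseConfig(threshold=tau))
            assert len(merged) == 1
            assert merged[0].sample_ids == ["s0", "s1"]

    def test_threshold_separates_dissimilar_sets(self, tissue_graph, tissue_ic):
        sets = _singleton_sets("T:3", "T:4")  # LIN ~ 0.317
        m = sample_similarity_matrix(sets, tissue_graph, SimilarityConfig(ic=tissue_ic))
        assert len(collapse(sets, m, CollapseConfig(threshold=0.3))) == 1
        assert len(collapse(sets, m, CollapseConfig(threshold=0.9))) == 2

    def test_zero_threshold_single_cluster(self, tissue_graph, tissue_ic):
        sets = _singleton_sets("T:3", "T:4", "T:2", "T:0")
        m = sample_similarity_matrix(sets, tissue_graph, SimilarityConfig(ic=tissue_ic))
        assert len(collapse(sets, m, CollapseConfig(threshold=0.0))) == 1

    def test_cluster_count_monotone_in_threshold(self):
        rng = np.random.default_rng(21)
        n = 15
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        ids = [f"s{i}" for i in range(n)]
        m = SampleSimilarityMatrix(ids, v)
        sets = [SemanticSet([i], frozenset(["T:3"])) for i in ids]
        counts = [len(collapse(sets, m, CollapseConfig(threshold=t)))
                  for t in np.arange(1.0, -0.01, -0.1)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 1

    def test_merged_label_reports_sample_counts(self, tissue_graph, tissue_ic):
        sets = [SemanticSet(["s0", "s1"], frozenset(["T:3"])),
                SemanticSet(["s2"], frozenset(["T:3", "T:2"]))]
        m = sample_similarity_matrix(sets, tissue_graph, SimilarityConfig(ic=tissue_ic))
        merged = collapse(sets, m, CollapseConfig(threshold=0.5), graph=tissue_graph)
        assert len(merged) == 1
        assert merged[0].label == "breast epithelium [3], mammary gland [1]"

    def test_threshold_validation(self, tissue_graph, tissue_ic):
        with pytest.raises(ValueError):
            CollapseConfig(threshold=1.5)


class TestPartOfNeutrality:
    def test_similarity_invariant_to_part_of_encoding(self, tmp_path):
        is_a_dir = tmp_path / "isa"
        part_dir = tmp_path / "part"
        tissue_isa, _ = make_toy_ontology(is_a_dir, part_of_variant=False)
        tissue_part, _ = make_toy_ontology(part_dir, part_of_variant=True)
        g1 = convert_part_of(parse_obo(tissue_isa))
        g2 = convert_part_of(parse_obo(tissue_part))
        ic1, ic2 = information_content(g1), information_content(g2)
        sets = _singleton_sets("T:3", "T:4", "T:2", "T:1")
        m1 = sample_similarity_matrix(sets, g1, SimilarityConfig(ic=ic1))
        m2 = sample_similarity_matrix(sets, g2, SimilarityConfig(ic=ic2))
        assert np.array_equal(m1.values, m2.values)
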