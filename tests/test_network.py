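"""Hypergeometric scoring, similarity networks, viral clusters, reference links."""

import itertools
import math

import pytest
from scipy import stats as sps

from soilvirome import (
    InputError,
    annotate_reference_links,
    build_network,
    form_viral_clusters,
    hypergeometric_pvalue,
)
from soilvirome.network import SimilarityEdge


def brute_pvalue(a, b, c, n):
    """P(|draw ∩ first-a| >= c) by enumeration of all b-subsets of n clusters."""
    first_a = set(range(a))
    hits = total = 0
    for draw in itertools.combinations(range(n), b):
        total += 1
        if len(first_a & set(draw)) >= c:
            hits += 1
    return hits / total


class TestHypergeometricPvalue:
    def test_closed_form_identical_triples(self):
        # both genomes have the same 3 clusters out of 10: p = 1/C(10,3)
        assert hypergeometric_pvalue(3, 3, 3, 10) == pytest.approx(1 / 120)

    def test_zero_shared_is_one(self):
        assert hypergeometric_pvalue(5, 4, 0, 20) == 1.0

    def test_invalid_bounds(self):
        with pytest.raises(InputError):
            hypergeometric_pvalue(3, 3, 4, 10)
        with pytest.raises(InputError):
            hypergeometric_pvalue(11, 3, 1, 10)

    def test_enumeration_oracle_small_instances(self):
        for n in (4, 7, 10):
            for a in range(1, n + 1):
                for b in range(1, n + 1):
                    for c in range(0, min(a, b) + 1):
                        assert hypergeometric_pvalue(a, b, c, n) == pytest.approx(
                            brute_pvalue(a, b, c, n), rel=1e-10, abs=1e-12
                        ), (a, b, c, n)

    def test_agrees_with_scipy_survival_function(self):
        for a, b, c, n in [(40, 35, 12, 200), (15, 80, 9, 120), (6, 6, 6, 400)]:
            want = float(sps.hypergeom.sf(c - 1, n, a, b))
            assert hypergeometric_pvalue(a, b, c, n) == pytest.approx(want, rel=1e-9)

    def test_monotone_in_shared_count(self):
        values = [hypergeometric_pvalue(8, 8, c, 30) for c in range(9)]
        assert all(x >= y for x, y in zip(values, values[1:]))


class TestBuildNetwork:
    def test_identical_genomes_strong_edge(self):
        clusters = {f"pc{i}" for i in range(10)}
        assignments = {"gA": clusters, "gB": clusters}
        # pad the universe so the overlap is surprising
        for i in range(20):
            assignments[f"ref{i}"] = {f"other{i}_{j}" for j in range(10)}
        (edge,) = [e for e in build_network(assignments) if {e.genome_a, e.genome_b} == {"gA", "gB"}]
        assert edge.shared == 10 and edge.score > 1

    def test_disjoint_genomes_never_edge(self):
        edges = build_network({"a": {"x"}, "b": {"y"}, "c": {"z"}})
        assert edges == []

    def test_toy_oracle_recomputation(self):
        """Six-genome network equals an independent recomputation of scores."""
        assignments = {
            "g1": {"a", "b", "c", "d"},
            "g2": {"a", "b", "c", "e"},
            "g3": {"f", "g", "h"},
            "g4": {"f", "g", "h", "i"},
            "g5": {"j", "k"},
            "g6": {"a", "k", "l", "m", "n"},
        }
        n = len(set().union(*assignments.values()))
        pairs = list(itertools.combinations(sorted(assignments), 2))
        want = []
        for ga, gb in pairs:
            c = len(assignments[ga] & assignments[gb])
            if c == 0:
                continue
            p = brute_pvalue(len(assignments[ga]), len(assignments[gb]), c, n)
            score = -math.log10(p * len(pairs))
            if score >= 1.0:
                want.append((ga, gb, c, pytest.approx(score, rel=1e-9)))
        got = [(e.genome_a, e.genome_b, e.shared, e.score) for e in build_network(assignments)]
        assert got == want

    def test_threshold_filtration_monotone(self):
        assignments = {
            f"g{i}": {f"pc{j}" for j in range(i, i + 4)} for i in range(8)
        }
        low = {(e.genome_a, e.genome_b) for e in build_network(assignments, threshold=0.0)}
        high = {(e.genome_a, e.genome_b) for e in build_network(assignments, threshold=2.0)}
        assert high <= low

    def test_relabelling_symmetry(self):
        assignments = {"x": {"a", "b"}, "y": {"b", "c"}, "z": {"c", "d"}}
        renamed = {f"n_{g}": cl for g, cl in assignments.items()}
        original = {
            frozenset((e.genome_a, e.genome_b)): (e.shared, e.score)
            for e in build_network(assignments, threshold=-10)
        }
        relabelled = {
            frozenset((e.genome_a[2:], e.genome_b[2:])): (e.shared, e.score)
            for e in build_network(renamed, threshold=-10)
        }
        assert original == relabelled

    def test_empty_cluster_set_rejected(self):
        with pytest.raises(InputError):
            build_network({"a": set(), "b": {"x"}})


class TestViralClusters:
    def edge(self, a, b):
        return SimilarityEdge(a, b, shared=1, pvalue=0.001, score=2.0)

    def test_no_edges_all_singletons(self):
        genomes = [f"g{i}" for i in range(5)]
        clusters = form_viral_clusters([], genomes)
        assert sorted(clusters.values()) == sorted(genomes)

    def test_path_is_transitive(self):
        clusters = form_viral_clusters(
            [self.edge("a", "b"), self.edge("b", "c")], ["a", "b", "c", "d"]
        )
        assert clusters["a"] == clusters["b"] == clusters["c"] == "a"
        assert clusters["d"] == "d"

    def test_planted_two_blocks_recovered(self):
        block1 = {f"A{i}": {f"pcA{j}" for j in range(6)} for i in range(4)}
        block2 = {f"B{i}": {f"pcB{j}" for j in range(6)} for i in range(4)}
        assignments = {**block1, **block2}
        # pad universe with singleton reference genomes sharing nothing
        for i in range(30):
            assignments[f"pad{i}"] = {f"pad_pc{i}"}
        edges = build_network(assignments)
        clusters = form_viral_clusters(edges, assignments)
        labels_a = {clusters[g] for g in block1}
        labels_b = {clusters[g] for g in block2}
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b


class TestReferenceLinks:
    def edge(self, a, b):
        return SimilarityEdge(a, b, shared=2, pvalue=1e-4, score=2.0)

    def test_no_references_matched_zero(self):
        frac, habitats = annotate_reference_links([], {}, ["c1", "c2"])
        assert frac == 0.0 and habitats == {}

    def test_all_matched_single_habitat(self):
        edges = [self.edge("c1", "refA"), self.edge("c2", "refA")]
        frac, habitats = annotate_reference_links(
            edges, {"refA": "soil"}, ["c1", "c2"]
        )
        assert frac == 1.0 and habitats == {"soil": 1.0}

    def test_partial_match_and_mixed_habitats(self):
        edges = [self.edge("c1", "refA"), self.edge("refB", "c1")]
        frac, habitats = annotate_reference_links(
            edges, {"refA": "soil", "refB": "aquatic"}, ["c1", "c2", "c3", "c4"]
        )
        assert frac == pytest.approx(0.25)
        assert habitats == {"aquatic": 1.0, "soil": 1.0}
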