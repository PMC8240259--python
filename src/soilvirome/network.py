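"""Gene-sharing similarity networks between viral genomes.

Two genomes are compared by the number of protein clusters they share.
Under the null hypothesis that each genome's clusters are drawn without
replacement from the pool of all ``n`` distinct clusters, the shared
count ``c`` for genomes with ``a`` and ``b`` clusters follows a
hypergeometric distribution; the pairwise similarity score is

    score = -log10( P(X >= c) * T )

where ``T`` is the number of genome pairs evaluated (a Bonferroni-style
correction).  Genome pairs with score >= 1 are considered remarkably
similar and retained as network edges; connected components of the
thresholded graph form viral clusters (VCs).

The p-value is computed by exact summation of hypergeometric terms on
the log scale, so it stays accurate far into the tail where naive
summation would underflow.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import InputError


def hypergeometric_pvalue(a: int, b: int, c: int, n: int) -> float:
    """Upper-tail probability P(X >= c), X ~ Hypergeometric(n, a, b).

    ``n`` is the population of distinct protein clusters, ``a`` and
    ``b`` the cluster counts of the two genomes, ``c`` the shared count.
    """
    if not (0 <= c <= min(a, b) <= n and a <= n and b <= n):
        raise InputError(f"invalid hypergeometric bounds a={a} b={b} c={c} n={n}")
    if c == 0:
        return 1.0
    lognorm = _log_comb(n, b)
    kmin = max(c, a + b - n)
    kmax = min(a, b)
    log_terms = [
        _log_comb(a, k) + _log_comb(n - a, b - k) - lognorm
        for k in range(kmin, kmax + 1)
    ]
    peak = max(log_terms)
    total = peak + math.log(sum(math.exp(t - peak) for t in log_terms))
    return min(1.0, math.exp(total))


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


@dataclass(frozen=True)
class SimilarityEdge:
    """A retained genome pair with its shared-cluster evidence."""

    genome_a: str
    genome_b: str
    shared: int
    pvalue: float
    score: float


def build_network(
    assignments: Mapping[str, Iterable[str]],
    threshold: float = 1.0,
    correction: str = "all",
) -> list[SimilarityEdge]:
    """Score all unordered genome pairs and retain edges with score >= threshold.

    ``assignments`` maps genome id -> its set of protein-cluster ids
    (each genome must have at least one).  ``correction`` chooses the
    pair count ``T`` in the score: ``"all"`` (default) counts every
    evaluated pair, ``"nonzero"`` only pairs sharing at least one
    cluster.  Pairs sharing nothing never form edges.
    """
    sets = {g: frozenset(cl) for g, cl in assignments.items()}
    for g, cl in sets.items():
        if not cl:
            raise InputError(f"genome {g!r} has no protein clusters")
    genomes = sorted(sets)
    if len(genomes) < 2:
        raise InputError("network needs at least 2 genomes")
    n = len(frozenset().union(*sets.values()))
    pairs = list(itertools.combinations(genomes, 2))
    if correction == "all":
        t = len(pairs)
    elif correction == "nonzero":
        t = sum(1 for ga, gb in pairs if sets[ga] & sets[gb])
    else:
        raise InputError(f"unknown correction {correction!r}")

    edges: list[SimilarityEdge] = []
    for ga, gb in pairs:
        shared = len(sets[ga] & sets[gb])
        if shared == 0:
            continue
        pvalue = hypergeometric_pvalue(len(sets[ga]), len(sets[gb]), shared, n)
        score = -(math.log10(pvalue) + math.log10(t)) if t > 0 else -math.log10(pvalue)
        if score >= threshold:
            edges.append(SimilarityEdge(ga, gb, shared, pvalue, score))
    return edges


def form_viral_clusters(
    edges: Iterable[SimilarityEdge], genomes: Iterable[str]
) -> dict[str, str]:
    """Connected components of the thresholded graph as genome -> cluster id.

    Singletons become singleton clusters; a cluster is named after its
    lexicographically smallest member, which makes ids deterministic.
    """
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    graph.add_edges_from((e.genome_a, e.genome_b) for e in edges)
    mapping: dict[str, str] = {}
    for component in nx.connected_components(graph):
        label = min(component)
        for genome in component:
            mapping[genome] = label
    return mapping


def annotate_reference_links(
    edges: Iterable[SimilarityEdge],
    reference_habitats: Mapping[str, str],
    study_genomes: Iterable[str],
) -> tuple[float, dict[str, float]]:
    """Fraction of study contigs linked to reference genomes, and habitats.

    Returns ``(matched_fraction, habitat_fractions)`` where
    ``matched_fraction`` is the share of study genomes with at least one
    edge to a reference, and ``habitat_fractions[h]`` is the share of
    *matched* contigs linked to at least one reference from habitat
    ``h`` (a contig linked to several habitats counts toward each).
    """
    study = sorted(set(study_genomes))
    study_set = set(study)
    if not study:
        raise InputError("no study genomes supplied")
    refs = set(reference_habitats)
    linked: dict[str, set[str]] = {}
    for e in edges:
        for s, r in ((e.genome_a, e.genome_b), (e.genome_b, e.genome_a)):
            if s in refs or s not in study_set:
                continue
            if r in refs:
                linked.setdefault(s, set()).add(reference_habitats[r])
    matched = [s for s in study if s in linked]
    matched_fraction = len(matched) / len(study)
    habitat_fractions: dict[str, float] = {}
    if matched:
        for habitat in sorted(set(reference_habitats.values())):
            habitat_fractions[habitat] = sum(
                1 for s in matched if habitat in linked[s]
            ) / len(matched)
    return matched_fraction, habitat_fractions


def to_graph(edges: Iterable[SimilarityEdge], genomes: Iterable[str] = ()) -> nx.Graph:
    """Materialise edges as a networkx graph (for GraphML export etc.)."""
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    for e in edges:
        graph.add_edge(e.genome_a, e.genome_b, shared=e.shared, pvalue=e.pvalue, score=e.score)
    return graph
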