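"""Spacer-protospacer matching, host-range summaries, polyvalence fractions."""

import numpy as np
import pytest

from soilvirome import (
    InputError,
    Spacer,
    UndefinedMetricError,
    match_spacers,
    polyvalent_fraction,
    reverse_complement,
    summarize_host_range,
)
from soilvirome.hosts import exact_match_evalue, min_length_for_evalue


def naive_links(contigs, spacers, min_len=20):
    """Exhaustive two-strand scan with Python substring search (the oracle)."""
    found = set()
    for sp in spacers:
        seq = sp.sequence.upper()
        if len(seq) < min_len or set(seq) - set("ACGT"):
            continue
        rc = reverse_complement(seq)
        for cid, contig in contigs.items():
            for query, strand in ((seq, "+"), (rc, "-")):
                if strand == "-" and rc == seq:
                    continue  # palindromes are reported once, on '+'
                start = contig.find(query)
                while start != -1:
                    found.add((cid, sp.genus, sp.spacer_id, start + 1, strand))
                    start = contig.find(query, start + 1)
    return found


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestMatchSpacers:
    def test_planted_forward_match(self):
        rng = np.random.default_rng(0)
        contig = random_seq(rng, 300)
        spacer = Spacer("s1", "gA", contig[100:130])
        (link,) = match_spacers({"c1": contig + "TTTT"}, [spacer])
        assert (link.position, link.strand, link.genus) == (101, "+", "gA")

    def test_planted_reverse_complement_match(self):
        rng = np.random.default_rng(1)
        contig = random_seq(rng, 300)
        spacer = Spacer("s1", "gA", reverse_complement(contig[50:82]))
        (link,) = match_spacers({"c1": contig}, [spacer])
        assert (link.position, link.strand) == (51, "-")
        sub = contig[link.position - 1 : link.position - 1 + link.length]
        assert reverse_complement(sub) == spacer.sequence

    def test_short_and_invalid_spacers_skipped(self):
        contig = "ACGT" * 50
        with pytest.warns(UserWarning, match="non-ACGT"):
            links = match_spacers(
                {"c": contig},
                [Spacer("bad", "g", "ACGTNACGTNACGTNACGTNACGTN"),
                 Spacer("short", "g", "ACGTACGTACGT")],
            )
        assert links == []

    def test_overlapping_occurrences_all_reported(self):
        contig = "A" * 60
        links = match_spacers({"c": contig}, [Spacer("s", "g", "A" * 20)])
        assert len(links) == 41  # 60 - 20 + 1, 'T'*20 palindome-free

    def test_oracle_equivalence_on_synthetic_contigs(self):
        rng = np.random.default_rng(42)
        contigs = {f"c{i:03d}": random_seq(rng, 2000) for i in range(30)}
        spacers = []
        ids = list(contigs)
        for j in range(40):  # planted
            cid = ids[int(rng.integers(len(ids)))]
            pos = int(rng.integers(0, 2000 - 30))
            seq = contigs[cid][pos : pos + 30]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            spacers.append(Spacer(f"p{j}", f"g{j % 5}", seq))
        for j in range(40):  # decoys
            spacers.append(Spacer(f"d{j}", f"g{j % 5}", random_seq(rng, 30)))
        got = {
            (l.contig_id, l.genus, l.spacer_id, l.position, l.strand)
            for l in match_spacers(contigs, spacers)
        }
        assert got == naive_links(contigs, spacers)

    def test_monotone_in_spacer_library(self):
        rng = np.random.default_rng(3)
        contigs = {"c": random_seq(rng, 1000)}
        first = Spacer("s1", "g1", contigs["c"][10:40])
        extra = Spacer("s2", "g2", contigs["c"][500:530])
        base = set(
            (l.spacer_id, l.position) for l in match_spacers(contigs, [first])
        )
        grown = set(
            (l.spacer_id, l.position) for l in match_spacers(contigs, [first, extra])
        )
        assert base <= grown

    def test_reverse_complement_symmetry(self):
        """Flipping every contig maps each link to the mirrored coordinate."""
        rng = np.random.default_rng(4)
        contigs = {"c": random_seq(rng, 500)}
        spacers = [
            Spacer("s1", "g", contigs["c"][100:130]),
            Spacer("s2", "g", reverse_complement(contigs["c"][300:330])),
        ]
        fwd = match_spacers(contigs, spacers)
        rev = match_spacers({"c": reverse_complement(contigs["c"])}, spacers)
        n = len(contigs["c"])
        mirrored = {
            (l.contig_id, l.spacer_id, n - (l.position + l.length - 1) + 1,
             "-" if l.strand == "+" else "+")
            for l in rev
        }
        assert {(l.contig_id, l.spacer_id, l.position, l.strand) for l in fwd} == mirrored


class TestHostRange:
    def links(self, pairs):
        return [
            type("L", (), dict(contig_id=c, genus=g, spacer_id=f"{c}{g}",
                               position=1, strand="+", length=30))()
            for c, g in pairs
        ]

    def test_single_genus_not_polyvalent(self):
        (s,) = summarize_host_range(self.links([("c1", "Pseudomonas")]))
        assert not s.polyvalent and s.n_genera == 1

    def test_two_genera_via_many_spacers(self):
        (s,) = summarize_host_range(
            self.links([("c1", "gA")] * 3 + [("c1", "gB")] * 2)
        )
        assert s.polyvalent and s.n_genera == 2

    def test_zero_link_contigs_omitted(self):
        assert summarize_host_range([]) == []

    def test_threshold_parameter(self):
        (s,) = summarize_host_range(
            self.links([("c1", "gA"), ("c1", "gB")]), min_genera=3
        )
        assert not s.polyvalent


class TestPolyvalentFraction:
    def summaries(self, flags):
        from soilvirome import HostRangeSummary

        return [
            HostRangeSummary(f"c{i}", frozenset({"a", "b"} if f else {"a"}),
                             2 if f else 1, f)
            for i, f in enumerate(flags)
        ]

    def test_all_polyvalent(self):
        assert polyvalent_fraction(self.summaries([True, True]), weighted=False) == 1.0

    def test_weighted_vs_count(self):
        s = self.summaries([True, False])
        tpm = {"c0": 30.0, "c1": 70.0}
        assert polyvalent_fraction(s, tpm) == pytest.approx(0.30)
        assert polyvalent_fraction(s, weighted=False) == pytest.approx(0.50)

    def test_empty_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            polyvalent_fraction([])

    def test_missing_abundance_is_input_error(self):
        with pytest.raises(InputError):
            polyvalent_fraction(self.summaries([True]), {"other": 1.0})


class TestEvalueReporting:
    def test_long_spacer_clears_threshold(self):
        # 40 nt exact match against a 100 Mb database
        assert exact_match_evalue(40, int(1e8)) < 1e-10
        # shorter matches are exponentially less significant
        assert exact_match_evalue(40, int(1e8)) < exact_match_evalue(30, int(1e8))

    def test_min_length_consistent(self):
        n = int(1e8)
        length = min_length_for_evalue(n, 1e-10)
        assert exact_match_evalue(length, n) < 1e-10
        assert exact_match_evalue(length - 1, n) >= 1e-10
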