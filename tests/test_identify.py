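"""Viral contig decision rules: length gate, detector categories, annotation criteria."""

from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilvirome import (
    InputError,
    apply_length_gate,
    classify_contig,
    classify_table,
    vhmm_criteria,
    virsorter_rule,
)

from conftest import make_contig


def oracle_classify(n_genes, n_vpf, n_ko, n_pfam, category, length=6000):
    """Independent evaluation of the quoted inequalities on exact rationals."""
    if length <= 5000:
        return False, "too_short"
    if category in (1, 2, 4, 5):
        return True, "virsorter"
    n = Fraction(n_genes)
    a = (
        n_vpf >= 5
        and Fraction(n_ko) / n < Fraction(1, 5)
        and Fraction(n_pfam) / n <= Fraction(2, 5)
        and Fraction(n_vpf) / n > Fraction(1, 10)
    )
    b = n_vpf >= n_pfam
    c = Fraction(n_vpf) / n >= Fraction(3, 5)
    for flag, route in ((a, "vhmm_a"), (b, "vhmm_b"), (c, "vhmm_c")):
        if flag:
            return True, route
    return False, "rejected"


class TestLengthGate:
    @pytest.mark.parametrize(
        "length,kept", [(5000, False), (5001, True), (4999, False), (100000, True)]
    )
    def test_strict_boundary(self, length, kept):
        contigs = [make_contig(n_genes=1, length=length)]
        assert (len(apply_length_gate(contigs)) == 1) is kept

    def test_empty_input(self):
        assert apply_length_gate([]) == []

    def test_counts_by_construction(self):
        contigs = [
            make_contig(n_genes=1, length=4000 + 50 * i, contig_id=f"c{i}")
            for i in range(100)
        ]
        short = sum(1 for c in contigs if c.length_nt <= 5000)
        assert len(apply_length_gate(contigs)) == 100 - short


class TestVirsorterRule:
    @pytest.mark.parametrize(
        "category,expected",
        [(1, True), (2, True), (3, False), (4, True), (5, True), (6, False), (None, False)],
    )
    def test_accepted_categories(self, category, expected):
        assert virsorter_rule(make_contig(category=category)) is expected

    @pytest.mark.parametrize("category", [0, 7, -1])
    def test_out_of_range_category(self, category):
        with pytest.raises(InputError):
            virsorter_rule(make_contig(category=category))


class TestAnnotationCriteria:
    def test_worked_example_criterion_a(self):
        # 20 genes, 5 VPF, 3 KO, 8 Pfam: 5>=5, 0.15<0.20, 0.40<=0.40, 0.25>0.10
        a, _, _ = vhmm_criteria(make_contig(20, n_vpf=5, n_ko=3, n_pfam=8))
        assert a

    @pytest.mark.parametrize(
        "kwargs,which,expected",
        [
            (dict(n_genes=20, n_vpf=5, n_ko=4, n_pfam=8), 0, False),  # KO at 20%
            (dict(n_genes=20, n_vpf=5, n_ko=3, n_pfam=9), 0, False),  # Pfam over 40%
            (dict(n_genes=50, n_vpf=5, n_ko=0, n_pfam=0), 0, False),  # VPF at 10%
            (dict(n_genes=10, n_vpf=4, n_pfam=4), 1, True),  # equality counts
            (dict(n_genes=10, n_vpf=3, n_pfam=4), 1, False),
            (dict(n_genes=10, n_vpf=6), 2, True),  # exactly 60%
            (dict(n_genes=10, n_vpf=5), 2, False),
        ],
    )
    def test_boundaries(self, kwargs, which, expected):
        assert vhmm_criteria(make_contig(**kwargs))[which] is expected

    def test_zero_genes_rejected(self):
        with pytest.raises(InputError):
            vhmm_criteria(make_contig(0))


class TestClassify:
    def test_detector_route_needs_no_annotation(self):
        res = classify_contig(make_contig(n_genes=1, category=1))
        assert res.is_viral and res.route == "virsorter"

    def test_no_vpf_with_pfam_never_viral(self):
        res = classify_contig(make_contig(10, n_vpf=0, n_pfam=10, category=3))
        assert not res.is_viral and res.route == "rejected"

    def test_route_order_first_satisfied(self):
        # satisfies (b) and (c) but not (a); route must be vhmm_b
        res = classify_contig(make_contig(10, n_vpf=10, n_ko=10, n_pfam=10))
        assert res.route == "vhmm_b"

    def test_exhaustive_oracle_equivalence(self):
        """Brute-force enumeration over all small contigs agrees with the rules."""
        categories = [None, 1, 2, 3, 4, 5, 6]
        mismatches = []
        for n in range(1, 7):
            for v in range(n + 1):
                for k in range(n + 1):
                    for p in range(n + 1):
                        for cat in categories:
                            res = classify_contig(
                                make_contig(n, n_vpf=v, n_ko=k, n_pfam=p, category=cat)
                            )
                            want_viral, want_route = oracle_classify(n, v, k, p, cat)
                            if (res.is_viral, res.route) != (want_viral, want_route):
                                mismatches.append((n, v, k, p, cat, res))
        assert not mismatches

    def test_gene_order_permutation_invariance(self):
        base = make_contig(6, n_vpf=3, n_ko=2, n_pfam=4)
        shuffled = type(base)(
            contig_id=base.contig_id,
            length_nt=base.length_nt,
            genes=tuple(reversed(base.genes)),
            virsorter_category=base.virsorter_category,
        )
        r1, r2 = classify_contig(base), classify_contig(shuffled)
        assert (r1.is_viral, r1.route) == (r2.is_viral, r2.route)

    @settings(derandomize=True, max_examples=200)
    @given(
        n=st.integers(1, 12),
        v=st.integers(0, 12),
        k=st.integers(0, 12),
        p=st.integers(0, 12),
    )
    def test_adding_vpf_hit_is_monotone(self, n, v, k, p):
        """An extra viral-protein-family hit can never veto a viral call."""
        v, k, p = min(v, n), min(k, n), min(p, n)
        before = classify_contig(make_contig(n, n_vpf=v, n_ko=k, n_pfam=p))
        if v < n:
            after = classify_contig(make_contig(n, n_vpf=v + 1, n_ko=k, n_pfam=p))
            assert after.is_viral >= before.is_viral


class TestClassifyTable:
    def test_matches_per_contig_classification(self, small_bundle):
        table = classify_table(
            small_bundle.annotations,
            small_bundle.virsorter,
            small_bundle.contig_lengths,
        )
        assert set(table.columns) >= {"contig_id", "is_viral", "route"}
        # spot-check agreement with the object API on a sample of contigs
        ann = small_bundle.annotations
        cats = dict(
            zip(small_bundle.virsorter["contig_id"], small_bundle.virsorter["category"])
        )
        for _, row in table.sample(30, random_state=0).iterrows():
            genes = ann[ann["contig_id"] == row["contig_id"]]
            contig = make_contig(0, length=len(small_bundle.contigs[row["contig_id"]]))
            n_vpf = genes["vpf_hit"].notna().sum()
            n_ko = genes["ko_hit"].notna().sum()
            n_pfam = genes["pfam_hit"].notna().sum()
            want = oracle_classify(
                len(genes), n_vpf, n_ko, n_pfam, cats.get(row["contig_id"]), contig.length_nt
            )
            assert (bool(row["is_viral"]), row["route"]) == want

    def test_category_validation(self):
        ann = pd.DataFrame(
            [{"gene_id": "g1", "contig_id": "c1", "start": 1, "end": 10,
              "strand": "+", "vpf_hit": None, "pfam_hit": None, "ko_hit": None,
              "eggnog_cat": None}]
        )
        with pytest.raises(InputError):
            classify_table(ann, {"c1": 9}, {"c1": 6000})
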