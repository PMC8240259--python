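"""Viral contig identification from assembler output plus annotation evidence.

Assembled contigs are classified as viral or not by explicit decision
rules operating on pre-computed evidence (no sequence search happens
here):

1. a strict length gate — only contigs longer than 5 kb are considered;
2. the detector-category rule — contigs placed in confidence categories
   1, 2, 4 or 5 by a VirSorter-style detector are accepted outright;
3. three annotation-based criteria over per-gene database hits
   (viral protein families (VPF), Pfam, KEGG KO), any one of which
   suffices:

   (a) ``n_vpf >= 5`` and ``n_ko/n_genes < 0.20`` and
       ``n_pfam/n_genes <= 0.40`` and ``n_vpf/n_genes > 0.10``;
   (b) ``n_vpf >= n_pfam`` (viral families at least as numerous as the
       putatively bacterial Pfam hits);
   (c) ``n_vpf >= 0.60 * n_genes``.

All fractional thresholds are evaluated with exact integer arithmetic
(cross-multiplication) so that boundary cases such as exactly 40% Pfam
coverage or exactly 60% VPF coverage are decided without floating-point
error.

By default "number of viral protein families" is interpreted as the
number of genes bearing a VPF hit; counting distinct family identifiers
instead is available via ``count_mode="families"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError

#: contigs must be strictly longer than this many nucleotides
MIN_CONTIG_LENGTH = 5000

#: detector confidence categories accepted as viral
VIRAL_VIRSORTER_CATEGORIES = frozenset({1, 2, 4, 5})

#: classification routes in the order they are tried
ROUTES = ("too_short", "virsorter", "vhmm_a", "vhmm_b", "vhmm_c", "rejected")


@dataclass(frozen=True)
class GeneAnnotation:
    """A predicted gene with its (optional) database hits.

    Coordinates are 1-based inclusive on the forward strand.  A gene may
    carry hits in several namespaces simultaneously; each namespace is
    counted independently.
    """

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    vpf_hit: str | None = None
    pfam_hit: str | None = None
    ko_hit: str | None = None
    eggnog_cat: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise InputError(
                f"gene {self.gene_id}: invalid coordinates [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class AnnotatedContig:
    """A contig with its genes and an optional detector category."""

    contig_id: str
    length_nt: int
    genes: tuple[GeneAnnotation, ...] = field(default_factory=tuple)
    sample_id: str | None = None
    virsorter_category: int | None = None

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise InputError(f"contig {self.contig_id}: non-positive length")
        object.__setattr__(self, "genes", tuple(self.genes))
        for g in self.genes:
            if g.end > self.length_nt:
                raise InputError(
                    f"gene {g.gene_id} extends past the end of contig {self.contig_id}"
                )


@dataclass(frozen=True)
class ViralCallResult:
    """Outcome of classifying one contig, with the counts the rules used."""

    contig_id: str
    is_viral: bool
    route: str
    n_genes: int
    n_vpf: int
    n_ko: int
    n_pfam: int


def apply_length_gate(
    contigs: Iterable[AnnotatedContig], min_length: int = MIN_CONTIG_LENGTH
) -> list[AnnotatedContig]:
    """Retain contigs strictly longer than ``min_length`` nucleotides."""
    return [c for c in contigs if c.length_nt > min_length]


def virsorter_rule(contig: AnnotatedContig) -> bool:
    """True iff the detector category is one of the accepted classes (1, 2, 4, 5).

    An absent category is missing evidence and yields False; a category
    outside 1..6 is an input error.
    """
    cat = contig.virsorter_category
    if cat is None:
        return False
    if cat not in range(1, 7):
        raise InputError(
            f"contig {contig.contig_id}: detector category {cat} outside 1..6"
        )
    return cat in VIRAL_VIRSORTER_CATEGORIES


def _hit_counts(contig: AnnotatedContig, count_mode: str) -> tuple[int, int, int, int]:
    genes = contig.genes
    if count_mode == "genes":
        n_vpf = sum(1 for g in genes if g.vpf_hit)
        n_ko = sum(1 for g in genes if g.ko_hit)
        n_pfam = sum(1 for g in genes if g.pfam_hit)
    elif count_mode == "families":
        n_vpf = len({g.vpf_hit for g in genes if g.vpf_hit})
        n_ko = len({g.ko_hit for g in genes if g.ko_hit})
        n_pfam = len({g.pfam_hit for g in genes if g.pfam_hit})
    else:
        raise InputError(f"unknown count_mode {count_mode!r}")
    return len(genes), n_vpf, n_ko, n_pfam


def vhmm_criteria(
    contig: AnnotatedContig, count_mode: str = "genes"
) -> tuple[bool, bool, bool]:
    """Evaluate the three annotation-based criteria on one contig.

    All coverage fractions use the total gene count as denominator and
    are compared with exact integer arithmetic.
    """
    n, n_vpf, n_ko, n_pfam = _hit_counts(contig, count_mode)
    if n == 0:
        raise InputError(
            f"contig {contig.contig_id}: annotation criteria need at least one gene"
        )
    a = (n_vpf >= 5) and (5 * n_ko < n) and (5 * n_pfam <= 2 * n) and (10 * n_vpf > n)
    b = n_vpf >= n_pfam
    c = 5 * n_vpf >= 3 * n
    return a, b, c


def classify_contig(
    contig: AnnotatedContig, count_mode: str = "genes"
) -> ViralCallResult:
    """Classify one contig, recording the first satisfied rule as its route.

    Rules are tried in fixed order: length gate, detector category,
    criteria (a), (b), (c).  A contig at or below the length gate gets
    route ``too_short`` regardless of its evidence.
    """
    n, n_vpf, n_ko, n_pfam = _hit_counts(contig, count_mode)
    if contig.length_nt <= MIN_CONTIG_LENGTH:
        return ViralCallResult(contig.contig_id, False, "too_short", n, n_vpf, n_ko, n_pfam)
    if virsorter_rule(contig):
        return ViralCallResult(contig.contig_id, True, "virsorter", n, n_vpf, n_ko, n_pfam)
    a, b, c = vhmm_criteria(contig, count_mode)
    if a:
        route, viral = "vhmm_a", True
    elif b:
        route, viral = "vhmm_b", True
    elif c:
        route, viral = "vhmm_c", True
    else:
        route, viral = "rejected", False
    return ViralCallResult(contig.contig_id, viral, route, n, n_vpf, n_ko, n_pfam)


def _hit_mask(col: pd.Series) -> pd.Series:
    return col.notna() & (col.astype(object) != "")


def classify_table(
    annotations: pd.DataFrame,
    virsorter: pd.DataFrame | Mapping[str, int],
    lengths: Mapping[str, int] | pd.Series,
    count_mode: str = "genes",
) -> pd.DataFrame:
    """Vectorised classification of a whole annotation table.

    Parameters
    ----------
    annotations:
        Per-gene table with columns ``gene_id, contig_id, start, end,
        strand, vpf_hit, pfam_hit, ko_hit, eggnog_cat`` (hit columns may
        contain NaN/empty for "no hit").
    virsorter:
        Either a DataFrame with columns ``contig_id, category`` or a
        mapping contig_id -> category; contigs absent from it have no
        detector prediction.
    lengths:
        Mapping contig_id -> length in nt, defining the contig universe.

    Returns
    -------
    DataFrame with one row per contig (in the order of ``lengths``) and
    columns ``contig_id, is_viral, route, n_genes, n_vpf, n_ko, n_pfam``.
    """
    lengths = pd.Series(dict(lengths) if not isinstance(lengths, pd.Series) else lengths)
    if isinstance(virsorter, pd.DataFrame):
        cats = pd.Series(
            virsorter["category"].values, index=virsorter["contig_id"].values
        )
    else:
        cats = pd.Series(dict(virsorter), dtype="float64")
    bad = cats[(cats < 1) | (cats > 6)]
    if len(bad):
        raise InputError(f"detector categories outside 1..6 for {list(bad.index)[:5]}")

    ann = annotations
    if count_mode == "genes":
        agg = pd.DataFrame(
            {
                "n_genes": ann.groupby("contig_id")["gene_id"].size(),
                "n_vpf": _hit_mask(ann["vpf_hit"]).groupby(ann["contig_id"]).sum(),
                "n_ko": _hit_mask(ann["ko_hit"]).groupby(ann["contig_id"]).sum(),
                "n_pfam": _hit_mask(ann["pfam_hit"]).groupby(ann["contig_id"]).sum(),
            }
        )
    elif count_mode == "families":
        grouped = ann.groupby("contig_id")
        agg = pd.DataFrame(
            {
                "n_genes": grouped["gene_id"].size(),
                "n_vpf": grouped["vpf_hit"].nunique(),
                "n_ko": grouped["ko_hit"].nunique(),
                "n_pfam": grouped["pfam_hit"].nunique(),
            }
        )
    else:
        raise InputError(f"unknown count_mode {count_mode!r}")

    df = agg.reindex(lengths.index).fillna(0).astype(int)
    df["length_nt"] = lengths
    cat = cats.reindex(lengths.index)
    n, n_vpf, n_ko, n_pfam = (
        df["n_genes"],
        df["n_vpf"],
        df["n_ko"],
        df["n_pfam"],
    )
    too_short = df["length_nt"] <= MIN_CONTIG_LENGTH
    vs = cat.isin(list(VIRAL_VIRSORTER_CATEGORIES))
    needs_vhmm = ~too_short & ~vs
    if (needs_vhmm & (n == 0)).any():
        missing = list(df.index[needs_vhmm & (n == 0)])[:5]
        raise InputError(
            f"contigs with no annotated genes cannot be evaluated: {missing}"
        )
    a = (n_vpf >= 5) & (5 * n_ko < n) & (5 * n_pfam <= 2 * n) & (10 * n_vpf > n)
    b = n_vpf >= n_pfam
    c = 5 * n_vpf >= 3 * n
    route = np.select(
        [too_short, vs, a, b, c],
        ["too_short", "virsorter", "vhmm_a", "vhmm_b", "vhmm_c"],
        default="rejected",
    )
    out = pd.DataFrame(
        {
            "contig_id": df.index,
            "is_viral": np.isin(route, ["virsorter", "vhmm_a", "vhmm_b", "vhmm_c"]),
            "route": route,
            "n_genes": n.values,
            "n_vpf": n_vpf.values,
            "n_ko": n_ko.values,
            "n_pfam": n_pfam.values,
        }
    ).reset_index(drop=True)
    return out
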