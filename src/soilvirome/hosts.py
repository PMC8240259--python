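"""CRISPR spacer -> protospacer host linkage and host-range (polyvalence) summaries.

Host prediction follows the exact-match convention: a viral contig is
linked to a bacterial genus when a CRISPR spacer archived in that genus's
spacer library occurs verbatim (full spacer length, 100% identity) on
either strand of the contig.  This realises the "BLASTn at E <= 1e-10
and 100% nucleotide identity" criterion as a minimum exact-match length:
for a perfect full-length match the E-value is a deterministic function
of match length and database size, and typical spacers (25-40 nt)
clear 1e-10 comfortably; :func:`exact_match_evalue` makes the nominal
E-value available for reporting.

A phage is called *polyvalent* (broad host range) when it is linked to
two or more distinct genera; the threshold is exposed as a parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InputError, UndefinedMetricError

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_ACGT = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Spacer:
    """A CRISPR spacer attributed to a host genus."""

    spacer_id: str
    genus: str
    sequence: str


@dataclass(frozen=True)
class HostLink:
    """One exact spacer occurrence on a viral contig.

    ``position`` is the 1-based start of the occurrence on the forward
    strand; for strand ``-`` the contig subsequence at that position
    equals the reverse complement of the spacer.
    """

    contig_id: str
    genus: str
    spacer_id: str
    position: int
    strand: str
    length: int


@dataclass(frozen=True)
class HostRangeSummary:
    contig_id: str
    linked_genera: frozenset[str]
    n_genera: int
    polyvalent: bool


def match_spacers(
    contigs: Mapping[str, str],
    spacers: Iterable[Spacer],
    min_len: int = 20,
) -> list[HostLink]:
    """Find every full-length exact spacer occurrence on either strand.

    Spacers shorter than ``min_len`` are ignored; spacers containing
    non-ACGT characters are skipped with a warning.  One
    :class:`HostLink` is emitted per occurrence (overlapping occurrences
    included).  Matching is windowed and hashed per spacer length, so the
    cost is linear in total contig length per distinct spacer length.
    """
    by_length: dict[int, dict[bytes, list[tuple[Spacer, str]]]] = {}
    for sp in spacers:
        seq = sp.sequence.upper()
        if set(seq) - _ACGT:
            warnings.warn(
                f"spacer {sp.spacer_id}: non-ACGT characters, record skipped",
                stacklevel=2,
            )
            continue
        if len(seq) < min_len:
            continue
        table = by_length.setdefault(len(seq), {})
        table.setdefault(seq.encode(), []).append((sp, "+"))
        rc = reverse_complement(seq)
        if rc != seq:  # palindromic spacers match once, reported on '+'
            table.setdefault(rc.encode(), []).append((sp, "-"))

    target_arrays = {
        length: np.sort(np.array(sorted(table.keys()), dtype=f"S{length}"))
        for length, table in by_length.items()
    }
    links: list[HostLink] = []
    for contig_id, seq in contigs.items():
        buf = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for length, table in by_length.items():
            if buf.size < length:
                continue
            windows = np.ascontiguousarray(sliding_window_view(buf, length))
            keys = windows.view(f"S{length}").ravel()
            targets = target_arrays[length]
            idx = np.searchsorted(targets, keys)
            idx[idx == targets.size] = 0
            hits = np.flatnonzero(targets[idx] == keys)
            for i in hits:
                for sp, strand in table[bytes(keys[i])]:
                    links.append(
                        HostLink(
                            contig_id=contig_id,
                            genus=sp.genus,
                            spacer_id=sp.spacer_id,
                            position=int(i) + 1,
                            strand=strand,
                            length=length,
                        )
                    )
    links.sort(key=lambda l: (l.contig_id, l.position, l.spacer_id, l.strand))
    return links


def summarize_host_range(
    links: Iterable[HostLink], min_genera: int = 2
) -> list[HostRangeSummary]:
    """Group links per contig; contigs with zero links are omitted."""
    genera: dict[str, set[str]] = {}
    for link in links:
        genera.setdefault(link.contig_id, set()).add(link.genus)
    return [
        HostRangeSummary(
            contig_id=cid,
            linked_genera=frozenset(gs),
            n_genera=len(gs),
            polyvalent=len(gs) >= min_genera,
        )
        for cid, gs in sorted(genera.items())
    ]


def polyvalent_fraction(
    summaries: Iterable[HostRangeSummary],
    abundance: Mapping[str, float] | pd.Series | None = None,
    weighted: bool = True,
) -> float:
    """Share of polyvalent phages among host-linked contigs.

    With ``weighted=True`` (default) the share is abundance-weighted
    (sum of TPM over polyvalent contigs divided by sum over all linked
    contigs); otherwise it is a plain contig-count ratio.
    """
    summaries = list(summaries)
    if not summaries:
        raise UndefinedMetricError("no host-linked contigs: polyvalent fraction undefined")
    if not weighted:
        return sum(s.polyvalent for s in summaries) / len(summaries)
    if abundance is None:
        raise InputError("weighted polyvalent fraction needs per-contig abundances")
    try:
        weights = np.array([abundance[s.contig_id] for s in summaries], dtype=float)
    except KeyError as exc:
        raise InputError(f"missing abundance for contig {exc.args[0]!r}") from exc
    total = weights.sum()
    if total <= 0:
        raise UndefinedMetricError("total abundance of linked contigs is zero")
    poly = np.array([s.polyvalent for s in summaries], dtype=bool)
    return float(weights[poly].sum() / total)


def exact_match_evalue(
    match_length: int,
    database_length: int,
    query_length: int | None = None,
    *,
    lam: float = 1.28,
    k: float = 0.46,
) -> float:
    """Karlin-Altschul E-value of a perfect nucleotide match.

    Uses ungapped nucleotide scoring with reward +1 (default
    ``lambda``/``K`` for the +1/-2 scheme), so the raw score of a perfect
    match equals its length: ``E = K * m * n * exp(-lambda * L)``.
    Intended for reporting which spacer lengths clear a given E-value
    threshold, not as a filter (matching is exact and full-length).
    """
    if match_length < 1 or database_length < 1:
        raise InputError("match and database lengths must be positive")
    m = query_length if query_length is not None else match_length
    return k * m * database_length * math.exp(-lam * match_length)


def min_length_for_evalue(
    database_length: int, evalue: float = 1e-10, **kwargs: float
) -> int:
    """Smallest exact-match length whose E-value is below ``evalue``."""
    for length in range(1, 1000):
        if exact_match_evalue(length, database_length, **kwargs) < evalue:
            return length
    raise InputError("no match length below 1000 clears the requested E-value")
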