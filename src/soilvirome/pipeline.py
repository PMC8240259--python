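"""End-to-end orchestration: bundle in, per-sample virome profile out.

The pipeline ties the individual analysis steps together in the order a
virome study applies them: viral contig classification, CRISPR host
linkage, lysogeny flagging, abundance normalisation and MRG screening.
:func:`measure_sample` holds the shared per-sample measurement logic so
that the synthetic-community generator can compute its ground-truth
manifest with exactly the same arithmetic the pipeline uses (the
round-trip tests rely on this equality being exact, not approximate).
"""

from __future__ import annotations

from typing import Any, Mapping

import pandas as pd

from .bundle import Bundle
from .errors import UndefinedMetricError
from .hosts import HostRangeSummary, match_spacers, polyvalent_fraction, summarize_host_range
from .identify import classify_table
from .lysogeny import (
    InductionMeasurement,
    flag_lysogenic,
    induced_per_cell,
    metagenome_integrase_pct,
    virome_lysogen_fraction,
)
from .markers import (
    DEFAULT_INTEGRASE_PFAMS,
    DEFAULT_REDUCTASE_KOS,
    DEFAULT_TRANSPORTER_KOS,
    MarkerGeneList,
)
from .profiling import compute_tpm, mrg_lysogen_attribution, screen_mrg

PROFILE_COLUMNS = [
    "n_viral_contigs",
    "n_host_linked",
    "lysogeny_fraction",
    "lysogeny_fraction_count",
    "polyvalence_fraction",
    "polyvalence_fraction_count",
    "transporter_pct",
    "reductase_pct",
    "on_lysogen_transporter",
    "on_lysogen_reductase",
    "integrase_pct",
    "induced_per_cell",
    "below_background",
]


def viral_calls(bundle: Bundle, count_mode: str = "genes") -> pd.DataFrame:
    """Classify every contig of a bundle (length gate + decision rules)."""
    return classify_table(
        bundle.annotations, bundle.virsorter, bundle.contig_lengths, count_mode
    )


def host_links(bundle: Bundle, viral_ids: set[str], min_spacer_len: int = 20):
    """Match all spacer libraries against the bundle's viral contigs."""
    viral_seqs = {cid: bundle.contigs[cid] for cid in bundle.contigs if cid in viral_ids}
    return match_spacers(viral_seqs, bundle.all_spacers(), min_len=min_spacer_len)


def measure_sample(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    viral_ids: set[str],
    lysogen_flags: pd.Series,
    host_genera: Mapping[str, frozenset[str] | set[str]],
    integrase_list: MarkerGeneList = DEFAULT_INTEGRASE_PFAMS,
    transporter_list: MarkerGeneList = DEFAULT_TRANSPORTER_KOS,
    reductase_list: MarkerGeneList = DEFAULT_REDUCTASE_KOS,
    induction: InductionMeasurement | None = None,
    measure_hosts: bool = True,
) -> dict[str, Any]:
    """Per-sample summary metrics from one count table plus global evidence.

    The feature universe of each metric follows from the count table
    itself: rows whose feature id is a gene id are genes, the rest are
    contigs; genes on viral contigs form the viral-gene universe, genes
    on other contigs the bacterial metagenome.  Undefined metrics
    (empty denominators) are reported as ``None``.
    """
    ann = annotations.set_index("gene_id")
    gene_ids = set(ann.index)
    is_gene = counts["feature_id"].isin(gene_ids)
    contig_rows = counts[~is_gene]
    gene_rows = counts[is_gene]

    out: dict[str, Any] = {key: None for key in PROFILE_COLUMNS}

    viral_rows = contig_rows[contig_rows["feature_id"].isin(viral_ids)]
    out["n_viral_contigs"] = int(len(viral_rows))
    contig_tpm = None
    if len(viral_rows):
        contig_counts = pd.Series(
            viral_rows["read_count"].values, index=viral_rows["feature_id"].values
        )
        contig_lengths = pd.Series(
            viral_rows["feature_length_nt"].values, index=viral_rows["feature_id"].values
        )
        try:
            contig_tpm = compute_tpm(contig_counts.astype(float), contig_lengths)
        except UndefinedMetricError:
            contig_tpm = None
        flags = lysogen_flags.reindex(contig_counts.index).fillna(False).astype(bool)
        out["lysogeny_fraction_count"] = virome_lysogen_fraction(flags, weighted=False)
        if contig_tpm is not None:
            out["lysogeny_fraction"] = virome_lysogen_fraction(flags, contig_tpm)

        if measure_hosts:
            summaries = [
                HostRangeSummary(
                    contig_id=cid,
                    linked_genera=frozenset(host_genera[cid]),
                    n_genera=len(host_genera[cid]),
                    polyvalent=len(host_genera[cid]) >= 2,
                )
                for cid in contig_counts.index
                if host_genera.get(cid)
            ]
            out["n_host_linked"] = len(summaries)
            if summaries:
                out["polyvalence_fraction_count"] = polyvalent_fraction(
                    summaries, weighted=False
                )
                if contig_tpm is not None:
                    try:
                        out["polyvalence_fraction"] = polyvalent_fraction(
                            summaries, contig_tpm
                        )
                    except UndefinedMetricError:
                        pass

    gene_contig = ann["contig_id"]
    parent = gene_rows["feature_id"].map(gene_contig)
    viral_gene_rows = gene_rows[parent.isin(viral_ids)]
    if len(viral_gene_rows):
        gtpm_counts = pd.Series(
            viral_gene_rows["read_count"].values,
            index=viral_gene_rows["feature_id"].values,
        ).astype(float)
        gtpm_lengths = pd.Series(
            viral_gene_rows["feature_length_nt"].values,
            index=viral_gene_rows["feature_id"].values,
        )
        try:
            gene_tpm = compute_tpm(gtpm_counts, gtpm_lengths)
        except UndefinedMetricError:
            gene_tpm = None
        ko_hits = ann["ko_hit"].reindex(gtpm_counts.index)
        if gene_tpm is not None:
            t_pct, r_pct = screen_mrg(gene_tpm, ko_hits, transporter_list, reductase_list)
            out["transporter_pct"] = t_pct
            out["reductase_pct"] = r_pct
        attribution = mrg_lysogen_attribution(
            ko_hits,
            gene_contig.reindex(gtpm_counts.index),
            lysogen_flags,
            transporter_list,
            reductase_list,
        )
        out["on_lysogen_transporter"] = attribution["transporter"]
        out["on_lysogen_reductase"] = attribution["reductase"]

    bact_gene_rows = gene_rows[~parent.isin(viral_ids)]
    if len(bact_gene_rows):
        btpm_counts = pd.Series(
            bact_gene_rows["read_count"].values,
            index=bact_gene_rows["feature_id"].values,
        ).astype(float)
        btpm_lengths = pd.Series(
            bact_gene_rows["feature_length_nt"].values,
            index=bact_gene_rows["feature_id"].values,
        )
        try:
            btpm = compute_tpm(btpm_counts, btpm_lengths)
            out["integrase_pct"] = metagenome_integrase_pct(
                btpm, ann["pfam_hit"].reindex(btpm.index), integrase_list
            )
        except UndefinedMetricError:
            pass

    if induction is not None:
        result = induced_per_cell(induction)
        out["induced_per_cell"] = result.induced_per_cell
        out["below_background"] = bool(result.below_background)
    return out


def run_pipeline(
    bundle: Bundle,
    integrase_list: MarkerGeneList = DEFAULT_INTEGRASE_PFAMS,
    transporter_list: MarkerGeneList = DEFAULT_TRANSPORTER_KOS,
    reductase_list: MarkerGeneList = DEFAULT_REDUCTASE_KOS,
    min_spacer_len: int = 20,
    count_mode: str = "genes",
    link_hosts: bool = True,
) -> pd.DataFrame:
    """Run the full analysis on a bundle; one profile row per sample.

    ``link_hosts=False`` skips the spacer-matching stage (the most
    expensive step) and leaves the polyvalence columns undefined.
    """
    calls = viral_calls(bundle, count_mode)
    viral_ids = set(calls.loc[calls["is_viral"], "contig_id"])
    lysogen_flags = flag_lysogenic(bundle.annotations, sorted(viral_ids), integrase_list)

    host_genera: dict[str, set[str]] = {}
    if link_hosts:
        links = host_links(bundle, viral_ids, min_spacer_len)
        for summary in summarize_host_range(links):
            host_genera[summary.contig_id] = set(summary.linked_genera)

    rows = {}
    for sample_id in bundle.sample_ids:
        counts = bundle.counts.get(sample_id)
        if counts is None:
            continue
        rows[sample_id] = measure_sample(
            counts,
            bundle.annotations,
            viral_ids,
            lysogen_flags,
            host_genera,
            integrase_list,
            transporter_list,
            reductase_list,
            induction=bundle.induction_for(sample_id),
            measure_hosts=link_hosts,
        )
    profile = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=PROFILE_COLUMNS
    )
    profile.index.name = "sample_id"
    profile.insert(
        0,
        "stress",
        bundle.samples.set_index("sample_id")["stress"].reindex(profile.index),
    )
    return profile.astype({c: float for c in profile.columns if c != "below_background"})
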