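"""TPM normalisation, MRG screening, and functional-category profiles of viromes.

Gene and contig abundances are expressed as TPM (transcripts per
million): read counts are first divided by feature length to give a
per-nucleotide rate, then rates are scaled to sum to one million over
the feature universe chosen for normalisation.  All percentage
quantities here use viral genes of one sample as the universe, since the
screened shares describe the virome, not the whole community.

Metal-resistance genes (MRGs) are recognised by KO identifier lists
(membrane transporters and reductases); the attribution step asks what
fraction of MRG genes sit on lysogen-flagged contigs, which is the key
evidence that lysogenic phages act as MRG reservoirs.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedMetricError
from .markers import MarkerGeneList

TPM_SCALE = 1_000_000.0


def compute_tpm(counts: pd.Series, lengths: pd.Series | Mapping[str, float]) -> pd.Series:
    """Length-normalised relative abundance scaled to one million.

    ``TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j)``; zero-count
    features get TPM 0.  Raises when every count is zero.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise InputError(f"missing lengths for features {missing}")
    if (lengths <= 0).any():
        raise InputError("feature lengths must be positive")
    if (counts < 0).any():
        raise InputError("negative read counts")
    rate = counts / lengths
    total = float(rate.sum())
    if total <= 0:
        raise UndefinedMetricError("all counts are zero: TPM undefined")
    return rate / total * TPM_SCALE


def screen_mrg(
    gene_tpm: pd.Series,
    ko_hits: pd.Series,
    transporter_list: MarkerGeneList,
    reductase_list: MarkerGeneList,
) -> tuple[float, float]:
    """Percent of viral-gene TPM hitting the transporter / reductase lists.

    Overlapping identifiers between the two lists trigger a warning and
    the gene is counted in both classes.
    """
    overlap = transporter_list.identifiers & reductase_list.identifiers
    if overlap:
        warnings.warn(
            f"{len(overlap)} KO ids present in both MRG lists; "
            "genes hitting them count toward both classes",
            stacklevel=2,
        )
    total = float(gene_tpm.sum())
    if total <= 0:
        raise UndefinedMetricError("total viral gene TPM is zero")
    hits = ko_hits.reindex(gene_tpm.index)
    t_pct = 100.0 * float(gene_tpm[hits.isin(transporter_list.identifiers)].sum()) / total
    r_pct = 100.0 * float(gene_tpm[hits.isin(reductase_list.identifiers)].sum()) / total
    return t_pct, r_pct


def mrg_lysogen_attribution(
    ko_hits: pd.Series,
    gene_contig: pd.Series,
    lysogen_flags: pd.Series,
    transporter_list: MarkerGeneList,
    reductase_list: MarkerGeneList,
    gene_tpm: pd.Series | None = None,
    weighted: bool = False,
) -> dict[str, float | None]:
    """Fraction of MRG genes located on lysogen-flagged viral contigs.

    Gene-count based by default; ``weighted=True`` weights genes by TPM.
    Classes with zero MRG genes get ``None`` (undefined).
    """
    gene_contig = gene_contig.reindex(ko_hits.index)
    on_lysogen = gene_contig.map(lysogen_flags).fillna(False).astype(bool)
    if weighted:
        if gene_tpm is None:
            raise InputError("weighted attribution needs gene TPM values")
        weight = gene_tpm.reindex(ko_hits.index).astype(float)
    else:
        weight = pd.Series(1.0, index=ko_hits.index)

    out: dict[str, float | None] = {}
    for cls, markers in (
        ("transporter", transporter_list),
        ("reductase", reductase_list),
    ):
        mask = ko_hits.isin(markers.identifiers)
        total = float(weight[mask].sum())
        if total <= 0:
            out[cls] = None
        else:
            out[cls] = float(weight[mask & on_lysogen].sum() / total)
    return out


def eggnog_category_profile(
    gene_tpm: pd.Series,
    eggnog_cats: pd.Series,
    none_label: str = "none",
) -> pd.Series:
    """TPM-weighted percentage of viral genes per COG category letter.

    Genes without a category are pooled under ``none``; percentages sum
    to 100 over the returned index.
    """
    total = float(gene_tpm.sum())
    if total <= 0:
        raise UndefinedMetricError("total viral gene TPM is zero")
    cats = eggnog_cats.reindex(gene_tpm.index)
    cats = cats.where(cats.notna() & (cats.astype(object) != ""), none_label)
    pct = gene_tpm.groupby(cats).sum() / total * 100.0
    return pct.sort_index()
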