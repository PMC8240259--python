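"""Lysogeny indicators: integrase carriage, metagenome prevalence, induction assay.

Three complementary indicators of lysogeny are computed per sample:

* the relative abundance of lysogenic phages in the free virome
  (TPM-weighted share of viral contigs carrying a phage-integrase gene);
* the relative abundance of phage integrase genes within the bacterial
  metagenome (percentage of total gene TPM);
* the number of phages chemically inducible per bacterial cell,
  ``X = (Vi - Vck) / B``, from a mitomycin-C induction assay where
  ``Vi``/``Vck`` are virus-like-particle counts with/without the
  inducing agent and ``B`` is bacterial abundance.

Integrase detection uses the Pfam namespace only; the marker list is an
argument so users can substitute their own curated families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, InputError, UndefinedMetricError
from .markers import MarkerGeneList
from .stats import kruskal_wallis


@dataclass(frozen=True)
class InductionMeasurement:
    """One induction-assay triplet: VLP counts with/without inducer, cells."""

    sample_id: str
    vi: float
    vck: float
    b: float

    def __post_init__(self) -> None:
        if self.vi < 0 or self.vck < 0:
            raise InputError(f"{self.sample_id}: negative VLP count")
        if self.b <= 0:
            raise InputError(f"{self.sample_id}: bacterial abundance must be > 0")


class InductionResult(NamedTuple):
    induced_per_cell: float
    below_background: bool


def flag_lysogenic(
    annotations: pd.DataFrame,
    contig_ids: Iterable[str],
    integrase_list: MarkerGeneList,
) -> pd.Series:
    """Boolean per contig: does any of its genes hit an integrase Pfam?

    ``contig_ids`` defines the universe (and order) of the result;
    contigs without any integrase hit are False.
    """
    if not integrase_list.identifiers:
        raise ConfigError("empty integrase list")
    if integrase_list.namespace != "pfam":
        raise ConfigError("integrase detection uses the Pfam namespace")
    contig_ids = list(contig_ids)
    hit = annotations["pfam_hit"].isin(integrase_list.identifiers)
    flagged = set(annotations.loc[hit, "contig_id"])
    return pd.Series([cid in flagged for cid in contig_ids], index=contig_ids, dtype=bool)


def virome_lysogen_fraction(
    flags: pd.Series,
    abundance: pd.Series | Mapping[str, float] | None = None,
    weighted: bool = True,
) -> float:
    """Share of lysogen-flagged contigs among all viral contigs of a sample.

    TPM-weighted by default; ``weighted=False`` gives the contig-count
    ratio.
    """
    if len(flags) == 0:
        raise UndefinedMetricError("empty virome: lysogen fraction undefined")
    if not weighted:
        return float(flags.sum() / len(flags))
    if abundance is None:
        raise InputError("weighted lysogen fraction needs per-contig abundances")
    weights = pd.Series(abundance).reindex(flags.index)
    if weights.isna().any():
        missing = list(weights.index[weights.isna()])[:5]
        raise InputError(f"missing abundance for contigs {missing}")
    total = float(weights.sum())
    if total <= 0:
        raise UndefinedMetricError("total viral abundance is zero")
    return float(weights[flags].sum() / total)


def metagenome_integrase_pct(
    gene_tpm: pd.Series,
    pfam_hits: pd.Series,
    integrase_list: MarkerGeneList,
) -> float:
    """Integrase share of the bacterial metagenome, in percent of total TPM."""
    if not integrase_list.identifiers:
        raise ConfigError("empty integrase list")
    total = float(gene_tpm.sum())
    if total <= 0:
        raise UndefinedMetricError("total gene TPM is zero")
    mask = pfam_hits.reindex(gene_tpm.index).isin(integrase_list.identifiers)
    return float(100.0 * gene_tpm[mask].sum() / total)


def induced_per_cell(m: InductionMeasurement) -> InductionResult:
    """Phages induced per bacterium, ``(Vi - Vck) / B``.

    A negative value (more VLPs in the control than the treatment) is
    returned unchanged with ``below_background=True`` so assay noise
    stays visible.
    """
    if m.b <= 0:
        raise InputError("bacterial abundance must be > 0")
    x = (m.vi - m.vck) / m.b
    return InductionResult(x, below_background=x < 0)


def gradient_trend(
    profiles: pd.DataFrame,
    stress: pd.Series | Sequence[float],
    groups: pd.Series | Sequence[str] | None = None,
    indicators: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Monotone direction and group test for each lysogeny indicator.

    For every indicator column, reports the Spearman correlation with
    the stress covariate (its sign is the trend direction) and a
    Kruskal-Wallis test across contamination groups.  If ``groups`` is
    not supplied, samples are binned into stress terciles labelled
    slight / moderate / high.
    """
    stress = pd.Series(np.asarray(stress, dtype=float), index=profiles.index)
    if groups is None:
        edges = np.quantile(stress, [1 / 3, 2 / 3])
        labels = np.select(
            [stress <= edges[0], stress <= edges[1]],
            ["slight", "moderate"],
            default="high",
        )
        groups = pd.Series(labels, index=profiles.index)
    else:
        groups = pd.Series(np.asarray(groups, dtype=object), index=profiles.index)
    if groups.nunique() < 2:
        raise InputError("gradient trend needs at least 2 contamination groups")
    if indicators is None:
        indicators = [c for c in profiles.columns if profiles[c].dtype.kind == "f"]

    rows = []
    for col in indicators:
        values = profiles[col].astype(float)
        ok = values.notna()
        rho, _ = sps.spearmanr(stress[ok], values[ok])
        grouped = {g: values[ok][groups[ok] == g].tolist() for g in groups[ok].unique()}
        grouped = {g: v for g, v in grouped.items() if v}
        if len(grouped) >= 2:
            kw = kruskal_wallis(grouped)
            h, df, p = kw.statistic, kw.df, kw.pvalue
        else:
            h, df, p = np.nan, 0, np.nan
        rows.append(
            {
                "indicator": col,
                "spearman_rho": float(rho) if rho == rho else np.nan,
                "direction": "increasing" if rho > 0 else ("decreasing" if rho < 0 else "flat"),
                "kw_H": h,
                "kw_df": df,
                "kw_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("indicator")
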