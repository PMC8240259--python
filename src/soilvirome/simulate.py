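"""Synthetic soil-virome communities with known ground truth.

The generator emits a complete input bundle (contigs, per-gene
annotations, detector categories, CRISPR spacer libraries, per-sample
count tables, induction triplets) whose statistical structure mirrors
what the analysis assumes about a heavy-metal stress gradient:

* each sample sits at a stress level in [0, 1] (by default seven
  samples whose spacing follows the log of available-Cr concentrations
  at two contaminated field sites);
* the probability that a phage is lysogenic (carries an integrase gene)
  and the probability that it is polyvalent (linked to >= 2 host
  genera) both follow logistic curves in stress;
* metal-resistance genes (MRGs) are planted on lysogenic contigs at a
  boosted rate, so MRGs concentrate on lysogens;
* host links are realised physically: a spacer-length substring of the
  viral contig is copied verbatim (either strand) into the linked
  genus's spacer library, plus a small fraction of random decoy spacers
  that match nothing;
* abundances are log-normal, scaled so each sample's counts sum to a
  configured library size;
* optionally (on by default), lysogenic phages at high stress withdraw
  from the free virome into host genomes ("prophage residency"): their
  virome abundance is down-weighted while the integrase share of the
  bacterial metagenome and the inducible phage yield rise.  This
  reproduces the characteristic pattern of a unimodal free-virome
  lysogen fraction alongside monotonically increasing
  integrase/induction indicators.

Every per-sample ground-truth quantity in the manifest is computed with
the same measurement code the pipeline uses
(:func:`soilvirome.pipeline.measure_sample`), applied to the planted
flags, so a noise-free analysis recovers the manifest exactly.

Nucleotide composition is i.i.d. uniform over ACGT: the decision rules
under test never look at sequence content except for exact spacer
matches, which are planted explicitly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bundle import ANNOTATION_COLUMNS, Bundle, GroundTruthManifest
from .errors import ConfigError
from .hosts import Spacer, reverse_complement
from .lysogeny import InductionMeasurement
from .markers import (
    DEFAULT_INTEGRASE_PFAMS,
    DEFAULT_REDUCTASE_KOS,
    DEFAULT_TRANSPORTER_KOS,
    MarkerGeneList,
)
from .pipeline import measure_sample

# Default seven-sample gradient: stress = log10(available Cr / min)
# rescaled to [0, 1] for the concentrations 0.11, 0.27, 6.76, 0.91,
# 6.09, 413.84 and 465.42 mg/kg at two field sites (three slightly,
# two moderately, two highly contaminated samples).
DEFAULT_SAMPLE_IDS = ("L1", "L2", "L3", "Z1", "Z2", "Z3", "Z4")
DEFAULT_STRESS_LEVELS = (0.0, 0.1075, 0.4932, 0.2531, 0.4807, 0.9859, 1.0)

# Synthetic genus tokens, with real-genus aliases for demonstration runs
# only; no pipeline logic may depend on these names.
GENUS_ALIASES = (
    "Pseudomonas",
    "Salmonella",
    "Cronobacter",
    "Enterobacter",
    "Escherichia",
    "Klebsiella",
    "Shigella",
    "Salinispora",
    "Micromonospora",
    "Actinomyces",
    "Bacillus",
    "Stenotrophomonas",
)

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_EGGNOG_LETTERS = tuple("CDEFGHIJKLMNOPQTUV")


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-min(x, 700.0)))
    z = math.exp(max(x, -700.0))
    return z / (1.0 + z)


def _clamp01(p: float) -> float:
    return min(1.0, max(0.0, p))


@dataclass(frozen=True)
class GradientConfig:
    """Parameters of the synthetic stress-gradient community.

    The logit pairs are (intercept, slope) of logistic curves in stress:
    ``P(lysogenic | s) = expit(a + b*s)`` and likewise for polyvalence
    and prophage residency.  ``n_viral_contigs`` is per sample.
    """

    stress_levels: tuple[float, ...] = DEFAULT_STRESS_LEVELS
    sample_ids: tuple[str, ...] | None = DEFAULT_SAMPLE_IDS
    n_samples: int | None = None
    n_host_genera: int = 12
    n_viral_contigs: int = 200
    contig_length_range: tuple[int, int] = (8000, 15000)
    genes_per_kb: float = 1.0
    lysogeny_logit: tuple[float, float] = (-2.2, 4.4)
    polyvalence_logit: tuple[float, float] = (-1.3, 1.5)
    mrg_rate_lytic: float = 0.05
    mrg_lysogen_boost: float = 8.0
    spacer_length: int = 32
    abundance_lognormal: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    # --- extensions beyond the core gradient parameters ---
    library_size: int = 1_000_000
    host_link_rate: float = 0.9
    decoy_spacer_fraction: float = 0.01
    prophage_residency: bool = True
    residency_logit: tuple[float, float] = (-6.0, 9.0)
    virsorter_route_fraction: float = 0.7
    n_bacterial_contigs: int = 40
    bacterial_length_range: tuple[int, int] = (3000, 9000)
    n_bacterial_integrase_genes: int = 3
    integrase_base_share: float = 0.001
    integrase_stress_gain: float = 0.008
    induction_x_scale: float = 26.0
    induction_noise_cv: float = 0.05
    integrase_list: MarkerGeneList = DEFAULT_INTEGRASE_PFAMS
    transporter_list: MarkerGeneList = DEFAULT_TRANSPORTER_KOS
    reductase_list: MarkerGeneList = DEFAULT_REDUCTASE_KOS

    def __post_init__(self) -> None:
        object.__setattr__(self, "stress_levels", tuple(float(s) for s in self.stress_levels))
        if self.n_samples is None:
            object.__setattr__(self, "n_samples", len(self.stress_levels))
        if self.n_samples != len(self.stress_levels):
            raise ConfigError("n_samples must equal len(stress_levels)")
        if any(not 0.0 <= s <= 1.0 for s in self.stress_levels):
            raise ConfigError("stress levels must lie in [0, 1]")
        if self.sample_ids is not None and len(self.sample_ids) != self.n_samples:
            raise ConfigError("sample_ids length must equal n_samples")
        if self.sample_ids is None:
            object.__setattr__(
                self,
                "sample_ids",
                tuple(f"S{i + 1}" for i in range(self.n_samples)),
            )
        lo, hi = self.contig_length_range
        if lo <= 5000:
            raise ConfigError(
                "contig_length_range minimum must exceed 5000 nt so generated "
                "viral contigs pass the length gate"
            )
        if hi < lo:
            raise ConfigError("contig_length_range must be (min, max) with min <= max")
        if self.genes_per_kb <= 0:
            raise ConfigError("genes_per_kb must be > 0")
        if not 0.0 <= self.mrg_rate_lytic <= 1.0:
            raise ConfigError("mrg_rate_lytic must lie in [0, 1]")
        if self.mrg_lysogen_boost < 1.0:
            raise ConfigError("mrg_lysogen_boost must be >= 1")
        if self.spacer_length < 20:
            raise ConfigError("spacer_length must be >= 20 nt")
        if self.spacer_length > lo:
            raise ConfigError("spacer_length exceeds the shortest possible contig")
        if not 0.0 <= self.host_link_rate <= 1.0:
            raise ConfigError("host_link_rate must lie in [0, 1]")
        if not 0.0 <= self.decoy_spacer_fraction <= 1.0:
            raise ConfigError("decoy_spacer_fraction must lie in [0, 1]")
        if not 0.0 <= self.virsorter_route_fraction <= 1.0:
            raise ConfigError("virsorter_route_fraction must lie in [0, 1]")
        if self.abundance_lognormal[1] < 0:
            raise ConfigError("abundance log-normal sigma must be >= 0")
        if self.n_host_genera < 2:
            raise ConfigError("need at least 2 host genera")
        if self.library_size < 1:
            raise ConfigError("library_size must be positive")
        if self.induction_noise_cv < 0:
            raise ConfigError("induction noise CV must be >= 0")
        if self.induction_x_scale < 0:
            raise ConfigError("induction X scale must be >= 0")

    def p_lysogenic(self, stress: float) -> float:
        a, b = self.lysogeny_logit
        return _clamp01(_expit(a + b * stress))

    def p_polyvalent(self, stress: float) -> float:
        a, b = self.polyvalence_logit
        return _clamp01(_expit(a + b * stress))

    def residency(self, stress: float) -> float:
        if not self.prophage_residency:
            return 0.0
        a, b = self.residency_logit
        return _clamp01(_expit(a + b * stress))

    def genus_names(self) -> list[str]:
        return [f"genus{i:02d}" for i in range(self.n_host_genera)]

    def genus_alias_table(self) -> dict[str, str]:
        """Synthetic genus token -> real genus name, for display only."""
        names = self.genus_names()
        return {
            g: GENUS_ALIASES[i % len(GENUS_ALIASES)] for i, g in enumerate(names)
        }

    def to_dict(self) -> dict:
        data = asdict(self)
        for key in ("integrase_list", "transporter_list", "reductase_list"):
            lst = getattr(self, key)
            data[key] = {
                "name": lst.name,
                "namespace": lst.namespace,
                "identifiers": sorted(lst.identifiers),
            }
        for key, value in list(data.items()):
            if isinstance(value, tuple):
                data[key] = list(value)
        return data


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _round_preserving_sum(raw: np.ndarray, total: int) -> np.ndarray:
    """Integer counts proportional to ``raw`` summing exactly to ``total``."""
    scaled = raw / raw.sum() * total
    floors = np.floor(scaled).astype(np.int64)
    remainder = int(total - floors.sum())
    if remainder > 0:
        order = np.argsort(-(scaled - floors), kind="stable")
        floors[order[:remainder]] += 1
    return floors


@dataclass
class _ContigDraft:
    contig_id: str
    sample_id: str
    length: int
    sequence: str
    genes: list[dict]
    virsorter_category: int | None
    lysogenic: bool
    hosts: tuple[str, ...]
    mrg_genes: list[dict]
    weight: float
    route: str


def _draw_viral_contig(
    cfg: GradientConfig,
    rng: np.random.Generator,
    contig_id: str,
    sample_id: str,
    p_lys: float,
    p_poly: float,
    residency: float,
    genera: list[str],
) -> _ContigDraft:
    lo, hi = cfg.contig_length_range
    length = int(rng.integers(lo, hi + 1))
    sequence = _random_sequence(rng, length)
    n_genes = max(3, int(round(length / 1000.0 * cfg.genes_per_kb)))
    slot = length // n_genes

    lysogenic = bool(rng.random() < p_lys)
    via_detector = bool(rng.random() < cfg.virsorter_route_fraction)
    if via_detector:
        category = int(rng.choice((1, 2, 4, 5)))
        vpf_mask = rng.random(n_genes) < 0.30
        route = "virsorter"
    else:
        category = None
        n_vpf = math.ceil(0.6 * n_genes)
        vpf_mask = np.zeros(n_genes, dtype=bool)
        vpf_mask[rng.choice(n_genes, n_vpf, replace=False)] = True
        route = "vhmm"

    pfam_mask = rng.random(n_genes) < 0.25
    ko_mask = rng.random(n_genes) < 0.15
    eggnog_mask = rng.random(n_genes) < 0.60

    genes: list[dict] = []
    for k in range(n_genes):
        start = k * slot + 1
        gene_len = int(rng.integers(300, max(301, min(1500, slot))))
        end = min(start + gene_len - 1, length)
        genes.append(
            {
                "gene_id": f"{contig_id}_g{k:03d}",
                "contig_id": contig_id,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "vpf_hit": f"VPF_{int(rng.integers(0, 300)):05d}" if vpf_mask[k] else None,
                "pfam_hit": f"PF{int(rng.integers(3000, 3300)):05d}" if pfam_mask[k] else None,
                "ko_hit": f"K9{int(rng.integers(0, 200)):04d}" if ko_mask[k] else None,
                "eggnog_cat": str(rng.choice(_EGGNOG_LETTERS)) if eggnog_mask[k] else None,
            }
        )

    if lysogenic:
        idx = int(rng.integers(n_genes))
        genes[idx]["pfam_hit"] = str(rng.choice(sorted(cfg.integrase_list.identifiers)))

    mrg_genes: list[dict] = []
    p_mrg = min(1.0, cfg.mrg_rate_lytic * (cfg.mrg_lysogen_boost if lysogenic else 1.0))
    if rng.random() < p_mrg:
        idx = int(rng.integers(n_genes))
        if rng.random() < 0.5:
            mrg_class, markers = "transporter", cfg.transporter_list
        else:
            mrg_class, markers = "reductase", cfg.reductase_list
        genes[idx]["ko_hit"] = str(rng.choice(sorted(markers.identifiers)))
        genes[idx]["eggnog_cat"] = "P"
        mrg_genes.append({"gene_id": genes[idx]["gene_id"], "class": mrg_class})

    hosts: tuple[str, ...] = ()
    if rng.random() < cfg.host_link_rate:
        n_hosts = 1
        if rng.random() < p_poly:
            n_hosts = 2 + int(rng.integers(0, 2))
        n_hosts = min(n_hosts, cfg.n_host_genera)
        picked = rng.choice(cfg.n_host_genera, size=n_hosts, replace=False)
        hosts = tuple(sorted(genera[i] for i in picked))

    mu, sigma = cfg.abundance_lognormal
    weight = float(rng.lognormal(mu, sigma))
    if lysogenic:
        weight *= 1.0 - residency

    return _ContigDraft(
        contig_id=contig_id,
        sample_id=sample_id,
        length=length,
        sequence=sequence,
        genes=genes,
        virsorter_category=category,
        lysogenic=lysogenic,
        hosts=hosts,
        mrg_genes=mrg_genes,
        weight=weight,
        route=route,
    )


def _draw_bacterial_contig(
    cfg: GradientConfig,
    rng: np.random.Generator,
    contig_id: str,
    sample_id: str,
    n_integrase: int,
) -> _ContigDraft:
    """A non-viral decoy contig; ``n_integrase`` of its genes carry integrase Pfams."""
    lo, hi = cfg.bacterial_length_range
    length = int(rng.integers(lo, hi + 1))
    sequence = _random_sequence(rng, length)
    n_genes = max(2, int(round(length / 1000.0 * cfg.genes_per_kb)))
    slot = length // n_genes
    category = int(rng.choice((3, 6))) if rng.random() < 0.5 else None

    genes: list[dict] = []
    for k in range(n_genes):
        start = k * slot + 1
        gene_len = int(rng.integers(300, max(301, min(1500, slot))))
        end = min(start + gene_len - 1, length)
        # gene 0 always carries a Pfam hit so criterion (b) can never fire
        has_pfam = k == 0 or rng.random() < 0.70
        genes.append(
            {
                "gene_id": f"{contig_id}_g{k:03d}",
                "contig_id": contig_id,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "vpf_hit": None,
                "pfam_hit": f"PF{int(rng.integers(3000, 3300)):05d}" if has_pfam else None,
                "ko_hit": f"K9{int(rng.integers(0, 200)):04d}" if rng.random() < 0.40 else None,
                "eggnog_cat": str(rng.choice(_EGGNOG_LETTERS)) if rng.random() < 0.60 else None,
            }
        )
    for k in range(min(n_integrase, n_genes)):
        genes[k]["pfam_hit"] = str(rng.choice(sorted(cfg.integrase_list.identifiers)))

    return _ContigDraft(
        contig_id=contig_id,
        sample_id=sample_id,
        length=length,
        sequence=sequence,
        genes=genes,
        virsorter_category=category,
        lysogenic=False,
        hosts=(),
        mrg_genes=[],
        weight=float(rng.lognormal(*cfg.abundance_lognormal)),
        route="bacterial",
    )


def generate_induction_triplets(
    b: Sequence[float],
    x: Sequence[float],
    noise_cv: float,
    vck: Sequence[float] | float = 1e5,
    sample_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[InductionMeasurement]:
    """Induction-assay triplets consistent with ``X = (Vi - Vck) / B``.

    ``Vi = Vck + X * B`` receives multiplicative log-normal noise with
    mean 1 and coefficient of variation ``noise_cv`` (so the recovered
    X is unbiased); ``Vck`` is the configured background VLP count.
    """
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    vck_arr = np.broadcast_to(np.asarray(vck, dtype=float), b.shape).copy()
    if b.shape != x.shape:
        raise ConfigError("B and X must have the same length")
    if np.any(b <= 0):
        raise ConfigError("bacterial abundances must be > 0")
    if np.any(x < 0) or np.any(vck_arr < 0):
        raise ConfigError("X and Vck must be >= 0")
    if noise_cv < 0:
        raise ConfigError("noise_cv must be >= 0")
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(len(b))]
    if rng is None:
        rng = np.random.default_rng(0)
    vi = vck_arr + x * b
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        vi = vi * rng.lognormal(-0.5 * sigma**2, sigma, size=vi.shape)
    return [
        InductionMeasurement(sample_id=sid, vi=float(v), vck=float(c), b=float(bb))
        for sid, v, c, bb in zip(sample_ids, vi, vck_arr, b)
    ]


def generate_community(config: GradientConfig | None = None) -> Bundle:
    """Generate a complete synthetic bundle with ground-truth manifest.

    Deterministic for a fixed ``config.seed``; running twice with the
    same configuration yields byte-identical output bundles.
    """
    cfg = config if config is not None else GradientConfig()
    rng = np.random.default_rng(cfg.seed)
    genera = cfg.genus_names()

    contigs: dict[str, str] = {}
    annotation_rows: list[dict] = []
    virsorter_rows: list[dict] = []
    spacers: dict[str, list[Spacer]] = {g: [] for g in genera}
    spacer_counter = {g: 0 for g in genera}
    counts: dict[str, pd.DataFrame] = {}
    manifest_contigs: dict[str, dict] = {}
    manifest_samples: dict[str, dict] = {}

    b_levels: list[float] = []
    x_levels: list[float] = []
    vck_levels: list[float] = []
    drafts_by_sample: dict[str, list[_ContigDraft]] = {}

    for sample_id, stress in zip(cfg.sample_ids, cfg.stress_levels):
        p_lys = cfg.p_lysogenic(stress)
        p_poly = cfg.p_polyvalent(stress)
        residency = cfg.residency(stress)

        drafts: list[_ContigDraft] = []
        for j in range(cfg.n_viral_contigs):
            draft = _draw_viral_contig(
                cfg,
                rng,
                f"{sample_id}_v{j:04d}",
                sample_id,
                p_lys,
                p_poly,
                residency,
                genera,
            )
            drafts.append(draft)
        remaining_integrase = cfg.n_bacterial_integrase_genes
        for j in range(cfg.n_bacterial_contigs):
            n_int = 1 if remaining_integrase > 0 else 0
            remaining_integrase -= n_int
            drafts.append(
                _draw_bacterial_contig(
                    cfg, rng, f"{sample_id}_b{j:03d}", sample_id, n_int
                )
            )
        drafts_by_sample[sample_id] = drafts

        for draft in drafts:
            contigs[draft.contig_id] = draft.sequence
            annotation_rows.extend(draft.genes)
            if draft.virsorter_category is not None:
                virsorter_rows.append(
                    {"contig_id": draft.contig_id, "category": draft.virsorter_category}
                )
            for genus in draft.hosts:
                pos = int(rng.integers(0, draft.length - cfg.spacer_length + 1))
                sub = draft.sequence[pos : pos + cfg.spacer_length]
                if rng.random() < 0.5:
                    sub = reverse_complement(sub)
                spacer_counter[genus] += 1
                spacers[genus].append(
                    Spacer(
                        spacer_id=f"{genus}_s{spacer_counter[genus]:05d}",
                        genus=genus,
                        sequence=sub,
                    )
                )
            if draft.route != "bacterial":
                manifest_contigs[draft.contig_id] = {
                    "sample_id": sample_id,
                    "lifestyle": "lysogenic" if draft.lysogenic else "lytic",
                    "hosts": list(draft.hosts),
                    "mrg_genes": draft.mrg_genes,
                    "route": draft.route,
                }

        counts[sample_id] = _sample_counts(cfg, rng, drafts, p_lys, residency)

        b_levels.append(10.0 ** (9.5 - 3.5 * stress))
        x_levels.append(cfg.induction_x_scale * p_lys * (0.1 + 0.9 * residency))
        vck_levels.append(0.05 * b_levels[-1])

    # decoy spacers: random sequences drawn from no contig
    for genus in genera:
        n_real = len(spacers[genus])
        n_decoys = max(1, int(round(cfg.decoy_spacer_fraction * n_real)))
        for d in range(n_decoys):
            spacers[genus].append(
                Spacer(
                    spacer_id=f"{genus}_decoy{d:03d}",
                    genus=genus,
                    sequence=_random_sequence(rng, cfg.spacer_length),
                )
            )

    induction_measurements = generate_induction_triplets(
        b_levels,
        x_levels,
        cfg.induction_noise_cv,
        vck=vck_levels,
        sample_ids=list(cfg.sample_ids),
        rng=rng,
    )
    induction = pd.DataFrame(
        [
            {"sample_id": m.sample_id, "vi": m.vi, "vck": m.vck, "b": m.b}
            for m in induction_measurements
        ]
    )

    annotations = pd.DataFrame(annotation_rows, columns=ANNOTATION_COLUMNS)
    virsorter = pd.DataFrame(virsorter_rows, columns=["contig_id", "category"])
    samples = pd.DataFrame(
        {"sample_id": list(cfg.sample_ids), "stress": list(cfg.stress_levels)}
    )

    # ground truth per sample, measured with the pipeline's own arithmetic
    for i, (sample_id, stress) in enumerate(zip(cfg.sample_ids, cfg.stress_levels)):
        drafts = drafts_by_sample[sample_id]
        viral_ids = {d.contig_id for d in drafts if d.route != "bacterial"}
        flags = pd.Series(
            {d.contig_id: d.lysogenic for d in drafts if d.route != "bacterial"}
        )
        host_genera = {
            d.contig_id: set(d.hosts) for d in drafts if d.route != "bacterial"
        }
        metrics = measure_sample(
            counts[sample_id],
            annotations,
            viral_ids,
            flags,
            host_genera,
            cfg.integrase_list,
            cfg.transporter_list,
            cfg.reductase_list,
            induction=None,
        )
        metrics.pop("induced_per_cell", None)
        metrics.pop("below_background", None)
        manifest_samples[sample_id] = {
            "stress": stress,
            "p_lysogeny": cfg.p_lysogenic(stress),
            "p_polyvalence": cfg.p_polyvalent(stress),
            "residency": cfg.residency(stress),
            "induced_per_cell": x_levels[i],
            **metrics,
        }

    manifest = GroundTruthManifest(
        config=cfg.to_dict(), contigs=manifest_contigs, samples=manifest_samples
    )
    return Bundle(
        contigs=contigs,
        annotations=annotations,
        virsorter=virsorter,
        spacers=spacers,
        counts=counts,
        induction=induction,
        samples=samples,
        manifest=manifest,
    )


def _sample_counts(
    cfg: GradientConfig,
    rng: np.random.Generator,
    drafts: Iterable[_ContigDraft],
    p_lys: float,
    residency: float,
) -> pd.DataFrame:
    """Per-sample feature counts: contigs plus genes, summing to library size.

    Viral gene counts follow their parent contig's weight scaled by
    length, so gene-level TPM mirrors contig-level abundance.  Bacterial
    gene rates are log-normal except for the integrase-bearing genes,
    whose total rate is pinned so the integrase TPM share of the
    bacterial metagenome equals ``integrase_base_share +
    integrase_stress_gain * P(lysogenic) * residency`` — the planted
    monotone metagenome trend.
    """
    mu, sigma = cfg.abundance_lognormal
    feature_ids: list[str] = []
    lengths: list[int] = []
    raw: list[float] = []

    bacterial_rates: dict[str, float] = {}
    integrase_gene_ids: list[str] = []
    for draft in drafts:
        feature_ids.append(draft.contig_id)
        lengths.append(draft.length)
        raw.append(draft.weight * draft.length)
        if draft.route == "bacterial":
            for gene in draft.genes:
                rate = float(rng.lognormal(mu, sigma))
                bacterial_rates[gene["gene_id"]] = rate
                if gene["pfam_hit"] in cfg.integrase_list.identifiers:
                    integrase_gene_ids.append(gene["gene_id"])

    target = cfg.integrase_base_share + cfg.integrase_stress_gain * p_lys * residency
    other_total = sum(
        r for g, r in bacterial_rates.items() if g not in integrase_gene_ids
    )
    int_total = sum(bacterial_rates[g] for g in integrase_gene_ids)
    if integrase_gene_ids and int_total > 0 and target < 1.0:
        scale = (target / (1.0 - target)) * other_total / int_total
        for g in integrase_gene_ids:
            bacterial_rates[g] *= scale

    for draft in drafts:
        for gene in draft.genes:
            gene_len = gene["end"] - gene["start"] + 1
            feature_ids.append(gene["gene_id"])
            lengths.append(gene_len)
            if draft.route == "bacterial":
                raw.append(bacterial_rates[gene["gene_id"]] * gene_len)
            else:
                raw.append(draft.weight * gene_len)

    read_counts = _round_preserving_sum(np.asarray(raw, dtype=float), cfg.library_size)
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "read_count": read_counts,
            "feature_length_nt": lengths,
        }
    )
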