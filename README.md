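# soilvirome

Analysis pipeline for profiling soil viromes and phage–bacterium
interactions along environmental stress gradients (e.g. heavy-metal
contamination), together with a synthetic community generator that
provides ground truth for validating every step.

## The scientific problem

Soil phages respond to environmental stress by shifting their
relationship with bacterial hosts: under harsh conditions (such as
chromium contamination) lysogeny becomes more common, broad-host-range
("polyvalent") phages gain ground, and phage genomes accumulate
auxiliary metabolic genes — notably metal-resistance genes (MRGs) —
that benefit their hosts. Detecting these shifts from shotgun
metagenomes requires a chain of explicit decision rules over assembled
contigs and their annotations. This package implements that chain as a
tested, reusable library:

* **Viral contig identification.** A contig (length > 5 kb, strictly)
  is called viral if a VirSorter-style detector places it in category
  1, 2, 4 or 5, or if its annotation profile satisfies any of three
  criteria over per-gene hits to viral protein families (VPF), Pfam
  and KEGG KO namespaces:
  (a) n_vpf ≥ 5 ∧ n_ko/n < 0.20 ∧ n_pfam/n ≤ 0.40 ∧ n_vpf/n > 0.10;
  (b) n_vpf ≥ n_pfam; (c) n_vpf ≥ 0.60·n.
  Fractions are compared with exact integer arithmetic, so boundary
  cases (exactly 40%, exactly 60%) are decided without floating-point
  error.
* **CRISPR host linkage.** A viral contig is linked to a host genus
  when a spacer from that genus's CRISPR library occurs verbatim
  (full length, 100% identity, either strand) on the contig. Phages
  linked to ≥ 2 genera are polyvalent; per-sample polyvalence is the
  TPM-weighted share of polyvalent phages among host-linked contigs.
* **Lysogeny indicators.** Contigs carrying a phage-integrase Pfam are
  lysogenic; the package reports the TPM-weighted lysogen share of the
  free virome, the integrase percentage of the bacterial metagenome,
  and the mitomycin-C induction yield X = (Vᵢ − V_ck)/B phages per
  cell.
* **MRG screening.** Membrane-transporter and reductase KOs are
  quantified as percentages of viral-gene TPM and attributed to
  lysogenic vs other phages.
* **Gene-sharing networks.** Genome pairs are scored by
  S = −log₁₀(P_hyper(X ≥ c) · T), where c is the number of shared
  protein clusters, the hypergeometric null draws the two genomes'
  clusters from the n distinct clusters in the analysis, and T is the
  number of evaluated pairs; edges require S ≥ 1 and connected
  components define viral clusters (VCs).
* **Community statistics.** Bias-corrected Chao1 and ACE richness,
  strict dominance filters, and the Kruskal–Wallis test for
  contamination-group comparisons.

TPM (transcripts per million) throughout is
TPMᵢ = 10⁶ · (cᵢ/lᵢ) / Σⱼ(cⱼ/lⱼ) over the feature universe being
normalised (viral contigs, viral genes, or bacterial genes of one
sample).

## Worked example

Generate a seven-sample synthetic community along the default stress
gradient and run the full pipeline:

```python
from soilvirome import GradientConfig, generate_community, run_pipeline, gradient_trend

cfg = GradientConfig(n_viral_contigs=120, seed=42, induction_noise_cv=0.0)
bundle = generate_community(cfg)
profile = run_pipeline(bundle)
print(profile[["stress", "lysogeny_fraction", "polyvalence_fraction",
               "integrase_pct", "induced_per_cell"]].round(3))
```

```
           stress  lysogeny_fraction  polyvalence_fraction  integrase_pct  induced_per_cell
sample_id
L1          0.000              0.106                 0.201          0.100             0.265
L2          0.108              0.172                 0.229          0.100             0.415
L3          0.493              0.446                 0.439          0.168             3.280
Z1          0.253              0.199                 0.253          0.104             0.795
Z2          0.481              0.384                 0.258          0.160             3.014
Z3          0.986              0.251                 0.498          0.778            22.138
Z4          1.000              0.254                 0.536          0.786            22.407
```

Reading the output: the lysogen share of the free virome rises with
stress and then falls at the most contaminated samples (Z3/Z4) — the
prophage-residency effect, where lysogens withdraw into host genomes —
while the integrase share of the bacterial metagenome (0.10% → 0.79%)
and the induction yield (0.27 → 22.4 phages per cell) keep rising.
Polyvalence climbs from ~20% to ~54% of host-linked phage abundance.
Trend statistics come from `gradient_trend(...)`, which reports the
Spearman direction and a Kruskal–Wallis test per indicator.

The same steps are available from the shell:

```bash
soilvirome simulate --seed 42 --out bundle/
soilvirome identify --bundle bundle/ --out viral_calls.tsv
soilvirome link-hosts --bundle bundle/ --out-dir bundle_out/
soilvirome report --bundle bundle/ --out report.tsv
```

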