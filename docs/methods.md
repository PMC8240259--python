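# Methods

This note documents the models, rules and design choices behind
`soilvirome`, in the order the pipeline applies them, followed by the
synthetic-community generator and its defaults.

## Viral contig identification

Inputs are a per-gene annotation table (hits in the viral-protein-family
(VPF), Pfam and KEGG KO namespaces, plus an eggNOG/COG category letter),
a detector-category table, and contig lengths. Contigs of length
≤ 5000 nt are excluded (strict inequality; route `too_short`). The
remaining contigs are accepted as viral by the first satisfied rule, in
fixed order:

1. `virsorter` — detector category ∈ {1, 2, 4, 5}. Categories 3 and 6
   (and an absent prediction) are not evidence.
2. `vhmm_a` — n_vpf ≥ 5 and n_ko/n < 0.20 and n_pfam/n ≤ 0.40 and
   n_vpf/n > 0.10, with n the total gene count of the contig.
3. `vhmm_b` — n_vpf ≥ n_pfam (equality counts).
4. `vhmm_c` — n_vpf ≥ 0.60·n (equality counts).

All fractional comparisons are evaluated by integer cross-multiplication
(e.g. `5*n_ko < n`), so the 10/20/40/60% boundaries are exact. "Number
of viral protein families" is interpreted as the number of genes bearing
a VPF hit; the same counting convention is applied to KO and Pfam. The
alternative reading (number of *distinct* family identifiers) is a
one-argument switch (`count_mode="families"`) because the two phrasings
are used interchangeably in the literature this rule set comes from. A
gene with hits in several namespaces counts toward each namespace
independently. The decision is a pure function of
(category, n, n_vpf, n_ko, n_pfam); the test suite verifies this against
an independent exact-rational oracle on an exhaustive enumeration of all
contigs with ≤ 6 genes.

## CRISPR host linkage

The field convention for spacer→protospacer assignment is BLASTn at
E ≤ 1e-10 and 100% nucleotide identity over the full spacer. For exact
full-length matches the E-value is a deterministic, monotone function of
match length and database size, so the criterion is realised as a
minimum exact-match length (default 20 nt, configurable); matching is
full-spacer-only on either strand, with coordinates reported 1-based on
the forward strand. A Karlin–Altschul calculator
(`hosts.exact_match_evalue`, ungapped +1/−2 nucleotide parameters
λ = 1.28, K = 0.46) is provided for reporting which lengths clear a
given E-value against a given database; it is not used as a filter.
Palindromic spacers match both strands at the same position and are
reported once, on the forward strand.

A phage is polyvalent when linked to ≥ 2 distinct genera (the threshold
is a parameter; the literature uses both "two or more" and "more than
two", and the ≥ 2 reading matches the parenthetical definition given
with the term). The per-sample polyvalent fraction is, by default, the
TPM-weighted share of polyvalent phages among host-linked viral contigs
— the quantity is an abundance, not a count — with a count-based
variant retained because published tallies of specific vs broad-range
contigs are counts. Whether published per-sample fractions are
abundance-weighted is generally unstated; the weighted form is the
default here and both are reported.

## Lysogeny indicators

* **Virome lysogen fraction** — a viral contig is lysogenic iff ≥ 1 of
  its genes hits a phage-integrase Pfam family (Pfam namespace only;
  KO-based detection is not attempted). The fraction is TPM-weighted
  over all viral contigs of the sample (count-based variant available).
* **Metagenome integrase share** — 100 × (TPM of bacterial genes
  hitting the integrase list) / (total bacterial-gene TPM). Whether
  such percentages should be TPM-weighted or gene-count ratios is
  unstated in the literature; TPM weighting is chosen for consistency
  with the rest of the abundance pipeline.
* **Induction yield** — X = (Vᵢ − V_ck)/B from one induction-assay
  triplet (VLP counts with and without mitomycin-C, bacterial
  abundance). The formula's control symbol appears in the literature
  both as V_c and V_ck; one control quantity is used. Negative X
  (treatment below control) is returned unchanged with a
  `below_background` flag rather than floored, so assay noise stays
  visible. X is invariant under joint rescaling of (Vᵢ, V_ck, B) by a
  common factor.

`gradient_trend` reports, per indicator, the sign of the Spearman
correlation with the stress covariate and a Kruskal–Wallis test across
contamination groups (terciles of stress if no grouping is given).

## Abundances and MRG screening

TPM is computed per normalisation universe:
TPMᵢ = 10⁶·(cᵢ/lᵢ)/Σⱼ(cⱼ/lⱼ), features with zero counts get 0, and the
sum over the universe is 10⁶ (relative tolerance 1e-6). The universes
are: viral contigs of a sample (lysogeny/polyvalence weighting), viral
genes of a sample (MRG and COG-category percentages — these quantities
describe the virome, so bacterial genes are excluded from the
denominator), and bacterial genes of a sample (integrase share).

MRG lists live in the KO namespace (transporters and reductases);
list files are namespace-tagged so Pfam-based lists also work.
The shipped default identifier sets are small placeholders for
synthetic benchmarks — real analyses must supply curated lists.
Overlapping transporter/reductase identifiers trigger a warning and the
gene counts toward both classes. MRG→lysogen attribution (the fraction
of MRG genes located on integrase-positive contigs) is gene-count based
by default, because the claim it supports is about where genes reside,
not how abundant they are; a TPM-weighted variant exists.

## Gene-sharing networks

Genomes are represented by sets of protein-cluster identifiers. For a
pair sharing c clusters, with a and b clusters respectively out of n
distinct clusters in the analysis, the similarity score is
S = −log₁₀(P(X ≥ c) · T) with X hypergeometric(n, a, b) and T the
number of evaluated genome pairs (all unordered pairs by default; a
"nonzero-only" T is switchable since either convention appears in
practice). The upper-tail probability is computed by exact term
summation on the log scale (log-gamma binomials + log-sum-exp), stable
deep into the tail. Edges require S ≥ 1; genomes sharing nothing never
form edges (P = 1 makes S ≤ 0 whenever T ≥ 1). Viral clusters are the
connected components of the thresholded graph — the cluster-formation
algorithm behind published VC counts is typically unstated, and MCL
could be substituted; components are the minimal deterministic choice,
with cluster ids named by the lexicographically smallest member.
Raising the threshold only removes edges, so clusters at a higher
threshold refine those at a lower one. In synthetic mode, protein
clusters are exact gene tokens from the generator; clustering real
protein sequences is out of scope.

## Community statistics

Chao1 (bias-corrected: S_obs + F₁(F₁−1)/(2(F₂+1)), defined even when
F₂ = 0; classic form switchable) and ACE (rare cutoff 10) delegate to
scikit-bio. When every rare species is a singleton the ACE coverage
estimate is zero and the function falls back to bias-corrected Chao1
with a warning. The dominance filter retains features whose relative
abundance strictly exceeds the threshold in at least one sample, with
an optional top-k cap. Kruskal–Wallis uses SciPy's implementation
(average-rank ties, tie-corrected H, chi-square p with k−1 df);
all-identical observations return H = 0, p = 1, and an exact
permutation p-value (complete enumeration of group assignments) is
available for N ≤ 10. No multiple-testing correction is applied by
default.

## Synthetic community generator

The generator emulates the statistical structure the analysis assumes,
not soil biology. Per sample at stress s ∈ [0, 1]:

* P(lysogenic) = expit(−2.2 + 4.4·s): ≈ 0.10 at s = 0, ≈ 0.90 at
  s = 1, matching the observed order-of-magnitude range of lysogen
  shares at clean vs heavily contaminated sites.
* P(polyvalent | host-linked) = expit(−1.3 + 1.5·s): ≈ 0.21 → 0.55,
  the span of published polyvalent fractions along such gradients.
* Prophage residency (on by default) r = expit(−6 + 9·s): essentially
  0 below mid-gradient, ≈ 0.95 at s = 1. Lysogenic contigs' virome
  abundance is multiplied by (1 − r), which makes the free-virome
  lysogen fraction rise and then fall while the bacterial integrase
  share (pinned to 0.1% + 0.8%·P(lys)·r of bacterial-gene TPM, the
  0.1–0.8% range seen in metagenomes) rises monotonically.
* MRG carriage: probability 0.05 on lytic contigs, ×8 (capped at 1) on
  lysogens, giving MRG-on-lysogen fractions in the 0.5–0.9 range that
  motivates the "lysogens as MRG reservoirs" claim.
* Induction truth X = 26·P(lys)·(0.1 + 0.9·r) phages per cell
  (≈ 0.3 → 22 across the gradient); emitted triplets satisfy
  Vᵢ = V_ck + X·B with mean-one log-normal noise of CV 0.05 (0 for
  noiseless runs), B = 10^(9.5−3.5·s) cells/g (the observed collapse of
  bacterial biomass along contamination gradients) and V_ck = 0.05·B.
* Abundances are log-normal(0, 1); counts are scaled to a library of
  10⁶ reads per sample with largest-remainder rounding so each count
  table sums exactly to the library size. A depth of 10⁶ keeps the
  integrase share's integer-rounding error (≲ 0.3% relative) far below
  the planted between-sample differences.
* Default gradient: seven samples whose stress values are the
  log-scaled available-Cr concentrations of two contaminated field
  sites (three slightly, two moderately, two highly contaminated), so
  demonstration runs have realistic spacing; 200 viral contigs per
  sample, lengths uniform in 8–15 kb (all above the 5 kb gate by
  construction), ~1 gene/kb, 12 host genera.

Host links are realised physically: each linked genus receives a
verbatim 32 nt substring of the contig, reverse-complemented with
probability 0.5 to exercise strand handling, plus ~1% random decoy
spacers per library to exercise the no-hit path. 70% of viral contigs
get a detector category from {1, 2, 4, 5}; the rest carry VPF hits on
⌈60%⌉ of their genes so they enter via criterion (c). Bacterial decoy
contigs (40 per sample, 3–9 kb, some below the length gate) carry
Pfam/KO background but no VPF hits, and at least one Pfam gene each, so
no identification rule can fire on them; three bacterial genes per
sample carry integrase Pfams and realise the metagenome integrase
share. Background hit identifiers are drawn from pools disjoint from
the marker lists, so marker detection is exact by construction.

Every per-sample manifest quantity is computed by the pipeline's own
measurement function (`pipeline.measure_sample`) applied to the planted
flags and the emitted count tables. This is deliberate: the round-trip
tests then check precisely the inversion the pipeline performs —
recovering flags, host sets and universes from the emitted files — with
exact (bitwise) equality, rather than comparing two independently
accumulated floating-point sums. Nucleotide composition is i.i.d.
uniform; genus names are synthetic tokens with an optional alias table
to real genus names for display only.

### What passing tests do and do not show

The generator realises exactly the evidence model the rules assume:
annotations are error-free, spacers are copied verbatim, marker lists
are complete, and every viral contig is identifiable by construction.
Passing the round-trip and calibration tests therefore demonstrates
that the implementation inverts its own generative assumptions
correctly — not that those assumptions hold for real soil data, where
annotation errors, partial spacer matches, incomplete marker lists,
chimeric assemblies and strain heterogeneity all blur the rules.
Study-scale headline numbers additionally depend on raw field reads
and versioned databases and are not reproducible at desk scale; the
validation is property-based for that reason.

## Numerical and degenerate-input conventions

* Empty denominators (no viral contigs, no host-linked contigs, no MRG
  genes, all-zero counts) raise `UndefinedMetricError` or yield
  `None`/NaN in tabular output — never silent zeros.
* Logistic probabilities are clamped to [0, 1] and the expit is
  saturated at |x| = 700 so degenerate configurations (intercept
  → ±∞) are exact.
* Problem sizes in the validation suite — exhaustive rule enumeration
  to 6 genes, spacer oracle at 200 × 500, hypergeometric enumeration to
  n = 12, 100 replicates for calibration/pattern checks, 10⁴
  null simulations — were chosen so each check runs in minutes on one
  CPU while keeping Monte-Carlo margins (binomial SE of the pass rates)
  well clear of the asserted thresholds.

## Known limitations

* Connected components, not MCL, define viral clusters; dense networks
  can chain distinct clusters together.
* The exact-match realisation of the spacer criterion cannot report
  near matches (e.g. single-mismatch protospacers) that BLASTn would.
* ACE's fallback to Chao1 changes the estimator exactly when the rare
  tail is all singletons; downstream comparisons should treat those
  samples with care.
* The CLI reads whole bundles into memory; it is sized for assembled
  contig sets, not raw reads.
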