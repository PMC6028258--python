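# Methods

This note documents the models, conventions and design choices behind
`amplicnv`, in the order data flows through the pipeline.

## Problem setting

Ampliconic genes occur in arrays of near-identical copies (>99.9%
within-array similarity), mostly on the X and Y chromosomes. Short-read
mappers cannot place reads on a specific copy, so per-copy genotyping is
impossible; what *is* measurable is aggregate signal: total read depth over
one collapsed copy (proportional to copy number) and allele-depth ratios at
variant sites (proportional to the fraction of copies carrying an allele).
Every statistic in this package is built on those two aggregates.

## Repeat discovery

`find_self_matches` reports maximal exact matches of a sequence against
itself, seeded by shared k-mers of length `min_exact` (default 100 bp)
taken at query positions on a `step` grid (default 100 bp) and extended in
both directions. This reproduces what an exact-seed self-alignment shows on
a dotplot. Exact seeding suffices because copies within an array diverge by
~0.1%/bp: an exact 100-mer survives between two copies with high
probability, and every ≥100 bp maximal repeat contains a grid-aligned seed
when `step` ≤ `min_exact`. The trivial main-diagonal match is excluded;
forward matches are canonicalized (query before target) and deduplicated.
Reverse-strand (palindrome) matches are detected and flagged but never used
for period inference, since tandem units are direct repeats.

`infer_unit` turns match offsets into a repeat unit. For a clean tandem
array of n copies of length L, off-diagonal offsets are exactly
{L, 2L, …, (n−1)L}; the smallest offset is the period and the number of
distinct multiples plus one is the copy count. When the offsets are not all
integer multiples (2% relative tolerance) of one period — interleaved or
nested repeat structures — the unit is flagged `ambiguous` and the smallest
candidate period is reported. Real unit boundaries are often curated
(defined by the repeated gene rather than the raw repeat), so a
user-supplied interval always overrides inference, and multi-unit regions
are handled by supplying multiple override intervals.

## Artificial reference

`build_reference` concatenates one copy of each repeat unit plus exactly
one single-copy control segment, with an invertible coordinate map to the
source assembly. Units are emitted as separate FASTA records by default
(simpler depth bookkeeping); a single concatenated record is available for
compatibility with single-contig workflows. For palindromic arrays the unit
convention is one gene copy ± 2 kb flanks (`unit_from_gene`). The control
is what defines "one copy": a whole-chromosome single-copy region (e.g. the
X excluding the pseudoautosomal regions, or an X-degenerate Y region) or a
single-copy control gene for autosomal arrays. The package takes the
control as a per-run configuration; it does not hard-code chromosome
classes.

## Depth and copy number

`depth_from_alignments` consumes a coordinate-sorted, indexed BAM and
filters reads the way the copy-number model assumes: mapping quality ≥ 50,
edit distance (NM) ≤ 2, no duplicates, secondary or supplementary
alignments. Both thresholds are configurable; NM ≤ 2 is the default
reading of "fewer than a couple of mismatches" and can be tightened to
≤ 1. Depth counts aligned reference bases only. A plain per-base TSV is
accepted as an alternative input, which is what the simulator produces.

`estimate_copy_number` is deliberately minimal: CN = median unit depth /
median control depth. Conventions that matter and are pinned by tests:

* zero-depth positions are **included** in the median (an absent unit must
  give CN 0);
* the median of an even count is the midpoint of the two central values;
* a zero control median yields a missing value with a warning, never ±inf;
* CN is never rounded to an integer — female X values are averages of two
  haplotypes and genuinely non-integer.

The estimator is scale-invariant (global depth rescaling cancels) and, at
per-copy depth ~40 over kb-scale units, recovers true CN to well under 0.1
copies on average; shorter units give noisier estimates because the median
of fewer Poisson draws has higher sampling variance. `duplicate_concordance`
quantifies robustness to sequencing replication, and `cn_summary` produces
the per-gene min/max/Δ/median view.

## Variant copies and the SFS

`polarize` assigns ancestral state from an outgroup allele: the outgroup
base must match ref or alt; a third allele or missing data excludes the
site from frequency analyses (status is kept, never silently dropped).

`variant_copies` estimates copies bearing the derived allele as
CN × derived-read fraction. Zero site depth is missing data, not zero
copies. The estimate is continuous; classification rounds half-up only
where integer copies are needed.

`classify_variants`: *common* ⇔ some individual carries ≥ 2 (rounded)
derived copies; *fixed* ⇔ derived read fraction ≥ 0.95 in every individual
with data (the threshold is a declared choice, configurable — read-fraction
data never shows exact fixation); *singleton* ⇔ exactly one derived copy in
the whole sample. `copy_weighted_sfs` replaces the per-chromosome allele
frequency with Σ derived copies / Σ gene copies over the sample and bins it
into left-closed deciles (a frequency of exactly 1 falls in the top bin).

## Selection tests

`annotate_ns_s` classifies SNVs against user-supplied CDS intervals by
codon translation under the standard genetic code, strand-aware; stop
gained/lost counts as nonsynonymous. MK α = 1 − (Ds·Pn)/(Dn·Ps) (NA when
Dn = 0 or Ps = 0) and DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps) (NA when a margin is
empty); NA propagates, it is never coerced to 0. Fisher's exact test is
two-sided by the summation-of-smaller-probabilities rule (scipy's
convention), which reproduces published p-values for these tables;
alternative two-sided conventions are deliberately not offered.
Benjamini–Hochberg correction excludes missing p-values from the number of
tests. Counts are per site, not copy-weighted, and populations are pooled
for MK (allele-frequency-free test; per-population MK is out of scope).

## Population structure

V_ST = (V_tot − V_within)/V_tot with V_within the size-weighted mean of
within-group variances, Σ V_i N_i / Σ N_i. The weighted form keeps
V_ST ≤ 1 and matches the V_ST literature; an unweighted switch exists
because published formula notations are sometimes ambiguous on this point.
Variances are sample variances (n−1) by default with a population-variance
(n) option; groups of size one contribute zero within-variance but count in
the weights. V_ST is invariant to affine transformations of CN, can dip
slightly below 0 by sampling, and the conventional 0.2 differentiation
cut-off is *reported* as a flag, never asserted. ANOVA is the standard
one-way fixed-effects F via scipy, FDR-corrected across genes; pairwise
gene–gene CN correlation is Pearson with BH correction across pairs;
class-level V_ST distributions are compared with the Wilcoxon rank-sum
test.

## Trees

p-distance = proportion of mismatching genotype calls over sites
non-missing in both individuals (haploid comparison — appropriate for male
X and Y; diploid genotypes would be compared as whole genotypes, not
alleles). Neighbor joining is the Saitou–Nei algorithm with the Q
criterion, rate-corrected branch lengths, negative lengths clamped to 0,
and ties broken by lowest (row, column) index for reproducibility. On
additive matrices the input distances are recovered exactly; agreement with
an independent NJ implementation (scikit-bio) is checked in the test suite.
Leaf annotations (copy numbers, geography, haplogroup) are embedded as
`[&key=value]` Newick comments plus a side-car TSV.

## Synthetic data

The generator emulates exactly the statistical structure the estimators
assume, with ground truth recorded:

* **reference**: per gene, a random unit sequence replicated `ref_copies`
  times with independent per-base mutations at the `divergence` rate
  (validated in [0, 0.5)), plus a unique control segment;
* **truth**: per-haplotype integer copy numbers ~ round(Normal(base_cn +
  population shift, cn_sd)), clipped ≥ 1; reported true CN is the
  per-chromosome mean, so diploid values can be half-integers;
* **depth**: Poisson(total CN × per-copy depth) per unit base and
  Poisson(ploidy × per-copy depth) per control base, independent across
  bases. Poisson is the simplest model consistent with the robustness the
  median-based estimator is designed for; an `overdispersion` knob switches
  to a gamma–Poisson (negative binomial) mixture with variance
  λ(1 + od·λ) since real coverage is somewhat overdispersed;
* **variants**: derived copies per individual either specified exactly or
  drawn as 1 + Binomial(CN − 1, copy_freq) for carriers
  (carrier_freq), guaranteeing derived ≤ CN; site depth is Poisson, derived
  reads Binomial(depth, derived/CN), so ref + alt always equals site depth;
* **outgroup**: ancestral allele, mutated with probability
  `outgroup_divergence` to one of the three other bases (which naturally
  produces third-allele polarization failures);
* **labels**: geographic population from the configuration, a haplogroup
  drawn from two per-population labels, sex by `female_fraction`.

Defaults describe the emulated study: seven geographic groups of 24 males
(a worldwide diversity-panel scale), per-copy depth 40 reads/base
(the panels' ~42× median genome-wide coverage), a 10 kb control, and four
genes whose unit lengths (6.8–17.1 kb) and copy numbers (2–23) follow
well-characterized Y ampliconic families from short high-copy TSPY-like
arrays to two-copy XKRY-like genes.

All randomness derives from one master seed through named `SeedSequence`
streams (truth / reference / depth / variants, with per-individual
substreams), so identical configurations give byte-identical outputs and
stages can be rerun independently.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artefacts (mappability, GC bias,
duplicates, soft-clipped incomplete copies), linkage between variants,
gene conversion between copies, and reference bias in variant calling.
Recovery results here certify the estimators given the model, not the
upstream mapping.

## Problem sizes in tests

The validation suite runs at reduced but statistically meaningful sizes
chosen to keep the full suite around a quarter minute: 100 replicate
individuals per copy-number recovery condition (true CN 1–8, 5 kb units),
200 replicates for variant-copy recovery, 50–100 random inputs per
brute-force-oracle comparison, tandem arrays up to 6 × 5 kb for repeat
discovery, and a 15-individual, 2-gene end-to-end pipeline run. These sizes
give Monte-Carlo standard errors an order of magnitude below the asserted
tolerances.

## Known limitations

* Repeat discovery assumes a dominant single period; complex nested
  structures are only flagged, not decomposed (use overrides).
* The k-mer self-match index is in-memory and suited to region-scale
  (≤ a few Mb) sequences, not whole genomes.
* Fixed-difference calling from read fractions depends on the 0.95
  threshold; very low-depth sites can misclassify.
* NJ is exact but O(n³)-ish in taxa; intended for panel-scale (hundreds)
  trees.
* The VCF reader requires biallelic SNVs with per-sample allelic depths.
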