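# amplicnv

Copy-number and coding-variant evolution of **ampliconic genes** — genes
present in many near-identical (>99.9% similar) tandem or palindromic
copies, concentrated on the mammalian X and Y chromosomes and typically
testis-expressed. Standard variant-calling and CNV pipelines fail on these
regions because short reads cannot be assigned to individual copies.
`amplicnv` implements the aggregate-depth strategy population geneticists
use instead, as a tested, reusable Python library with a thin CLI.

## The method

**Copy number.** All copies of a gene are collapsed onto a single repeat
unit in a short *artificial reference* (one unit per gene plus a
single-copy control gene). After mapping, reads from every copy pile up on
the one unit, so for individual *i* and gene *g*:

    CN_ig = median(depth over unit g) / median(depth over control)

The median makes the estimate robust; the control ratio cancels the
individual's overall sequencing depth.

**Repeat units** are found by exact self-matching (maximal exact matches
≥ 100 bp seeded on a 100 bp grid — the automated counterpart of a dotplot):
off-diagonal match offsets are multiples of the repeat period, giving the
unit length and copy count. Curated unit intervals can always override
inference, including the gene ± 2 kb convention for palindromic arrays.

**Variant copies.** Variants are called against the artificial reference
without allele-balance filtering and polarized with an outgroup. The number
of copies bearing the derived allele is

    derived_copies = CN_ig × (derived-allele reads / reads at the site)

**Statistics on top:** a copy-number-weighted site frequency spectrum
(Σ derived copies / Σ gene copies over the sample), McDonald–Kreitman
α = 1 − (Ds·Pn)/(Dn·Ps), direction of selection
DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps), two-sided Fisher exact tests with
Benjamini–Hochberg FDR, the copy-number differentiation index
V_ST = (V_tot − Σ V_i N_i / Σ N_i)/V_tot, one-way ANOVA of CN on
geography/haplogroup, and Saitou–Nei neighbor-joining trees on genotype
p-distances.

A first-class synthetic-data generator (`amplicnv.simulate`) produces every
input with known ground truth — tandem-array references, Poisson per-base
depth, binomial allele depths, outgroup alleles, sample metadata — so each
estimator is validated by parameter recovery.

## Worked example

```python
from amplicnv import MKCounts, mk_test, pool_counts

counts = [MKCounts("BPY2", 3, 0, 2, 2), MKCounts("CDY", 14, 6, 14, 7),
          MKCounts("HSFY", 3, 1, 9, 1), MKCounts("PRY", 0, 5, 6, 0),
          MKCounts("RBMY1A1", 23, 10, 20, 7)]
print(mk_test(counts).round(3).to_string(index=False))
```

prints

```
   gene  Pn  Ps  Dn  Ds  alpha    DoS  fisher_p  fdr_q
   BPY2   3   0   2   2    NaN -0.500     0.429  0.842
    CDY  14   6  14   7 -0.167 -0.033     1.000  1.000
   HSFY   3   1   9   1  0.667  0.150     0.505  0.842
    PRY   0   5   6   0  1.000  1.000     0.002  0.011
RBMY1A1  23  10  20   7  0.195  0.044     0.779  0.974
```

Each row is one Y-linked ampliconic gene's polymorphic/fixed NS and S site
counts. α > 0 and DoS > 0 would indicate an excess of adaptive
nonsynonymous fixations; NaN marks tables where α is undefined (zero Dn or
Ps). Only PRY shows a significant NS/S asymmetry, and the FDR column
corrects across the genes tested.

The `examples/` directory has one short script per capability
(copy-number estimation, repeat discovery, variant copies + SFS, selection
tests, V_ST/ANOVA, NJ trees, and the full pipeline); each prints its
numbers with a note on what they mean. The same stages are exposed as CLI
subcommands: `amplicnv simulate | discover | buildref | cn | varcn | mk |
structure | tree | run`.

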