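"""Selection tests on coding variation: McDonald-Kreitman and friends.

Counts of nonsynonymous (NS) and synonymous (S) variants, split into
polymorphisms (P) and fixed differences against the outgroup (D), feed
the classical 2x2 machinery:

* McDonald-Kreitman alpha = 1 - (Ds*Pn)/(Dn*Ps), the estimated fraction
  of nonsynonymous fixations driven by positive selection,
* DoS (direction of selection) = Dn/(Dn+Ds) - Pn/(Pn+Ps), positive under
  adaptive evolution and negative under segregating slightly deleterious
  variation (defined even when a cell is zero),
* a two-sided Fisher exact test on the 2x2 table, with
  Benjamini-Hochberg FDR across genes.

Undefined statistics are returned as NaN, never coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class MKCounts:
    """Polymorphic/fixed NS and S site counts for one gene (or a pool)."""

    gene_id: str
    pn: int
    ps: int
    dn: int
    ds: int

    def __post_init__(self):
        if min(self.pn, self.ps, self.dn, self.ds) < 0:
            raise ValueError("MK counts must be non-negative")

    def __add__(self, other: "MKCounts") -> "MKCounts":
        return MKCounts("pooled", self.pn + other.pn, self.ps + other.ps,
                        self.dn + other.dn, self.ds + other.ds)


@dataclass(frozen=True)
class CDS:
    """A coding sequence on a reference segment: ordered exon intervals.

    Intervals are 0-based half-open on the segment; for strand "-" the
    coding order runs through the reverse complement.
    """

    exons: tuple[tuple[int, int], ...]
    strand: str = "+"

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def annotate_ns_s(pos: int, ref: str, alt: str, cds: CDS, sequence: str) -> str:
    """Classify a SNV as "NS", "S" or "non-coding" under the standard code.

    ``pos`` is 0-based on ``sequence``.  NS aggregates missense plus stop
    gained/lost.  Indels are rejected; variants outside the exons are
    non-coding.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only single-nucleotide variants can be classified")
    offset, hit = 0, None
    for start, end in cds.exons:
        if start <= pos < end:
            hit = offset + (pos - start)
            break
        offset += end - start
    if hit is None:
        return "non-coding"

    coding = "".join(sequence[s:e] for s, e in cds.exons)
    coding_ref = coding[:hit] + ref + coding[hit + 1:]
    coding_alt = coding[:hit] + alt + coding[hit + 1:]
    if cds.strand == "-":
        coding_ref = str(Seq(coding_ref).reverse_complement())
        coding_alt = str(Seq(coding_alt).reverse_complement())
        hit = len(coding) - 1 - hit
    codon_i = hit // 3
    c_ref = coding_ref[3 * codon_i: 3 * codon_i + 3]
    c_alt = coding_alt[3 * codon_i: 3 * codon_i + 3]
    if len(c_ref) < 3:
        return "non-coding"  # trailing partial codon
    aa_ref = str(Seq(c_ref).translate())
    aa_alt = str(Seq(c_alt).translate())
    return "S" if aa_ref == aa_alt else "NS"


def mk_alpha(counts: MKCounts) -> float:
    """alpha = 1 - (Ds*Pn)/(Dn*Ps); NaN when Dn or Ps is zero."""
    if counts.dn == 0 or counts.ps == 0:
        return float("nan")
    return 1.0 - (counts.ds * counts.pn) / (counts.dn * counts.ps)


def direction_of_selection(counts: MKCounts) -> float:
    """DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps); NaN when either margin is empty."""
    d, p = counts.dn + counts.ds, counts.pn + counts.ps
    if d == 0 or p == 0:
        return float("nan")
    return counts.dn / d - counts.pn / p


def fisher_exact_2x2(counts: MKCounts) -> float:
    """Two-sided Fisher exact p on [[Pn, Ps], [Dn, Ds]].

    Two-sided by summation of all tables (with the observed margins)
    whose hypergeometric probability does not exceed the observed
    table's.  An all-zero table has p = 1.
    """
    p = stats.fisher_exact([[counts.pn, counts.ps], [counts.dn, counts.ds]],
                           alternative="two-sided").pvalue
    return float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries pass through.

    Missing p-values are excluded from the number of tests m, matching an
    analysis that only corrects the tests actually performed.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def pool_counts(counts: list[MKCounts], label: str = "pooled") -> MKCounts:
    """Element-wise sum of per-gene counts (the pooled-region test input)."""
    tot = MKCounts(label, 0, 0, 0, 0)
    for c in counts:
        tot = tot + c
    return MKCounts(label, tot.pn, tot.ps, tot.dn, tot.ds)


def mk_test(counts: list[MKCounts], fdr: bool = True) -> pd.DataFrame:
    """alpha, DoS, Fisher p (and BH q across genes) for a batch of counts."""
    rows = []
    for c in counts:
        rows.append((c.gene_id, c.pn, c.ps, c.dn, c.ds,
                     mk_alpha(c), direction_of_selection(c), fisher_exact_2x2(c)))
    out = pd.DataFrame(rows, columns=["gene", "Pn", "Ps", "Dn", "Ds",
                                      "alpha", "DoS", "fisher_p"])
    if fdr:
        out["fdr_q"] = bh_fdr(out["fisher_p"])
    return out


def counts_from_classification(
    classified: pd.DataFrame,
    variant_classes: pd.DataFrame,
) -> list[MKCounts]:
    """Assemble per-gene MK counts from classified, NS/S-annotated variants.

    ``classified`` carries variant_id and status (fixed/polymorphic);
    ``variant_classes`` carries variant_id, gene and var_class ("NS"/"S").
    Each variant counts once, regardless of its copy number.
    """
    df = classified.merge(variant_classes[["variant_id", "gene", "var_class"]], on="variant_id")
    df = df[df["var_class"].isin(["NS", "S"])]
    out = []
    for gene, sub in df.groupby("gene", sort=False):
        tab = {(st, vc): 0 for st in ("polymorphic", "fixed") for vc in ("NS", "S")}
        for _, r in sub.iterrows():
            if r.status in ("polymorphic", "fixed"):
                tab[(r.status, r.var_class)] += 1
        out.append(MKCounts(gene, tab[("polymorphic", "NS")], tab[("polymorphic", "S")],
                            tab[("fixed", "NS")], tab[("fixed", "S")]))
    return out
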