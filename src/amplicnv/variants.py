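"""Outgroup polarization and per-variant copy estimation.

A variant called against the artificial reference aggregates all copies of
a gene, so its read fractions carry copy information: the number of gene
copies bearing the derived allele is estimated as

    derived_copies = gene_CN x (reads supporting the derived allele)
                             / (reads covering the site)

after polarizing each site with an outgroup allele.  From the per-individual
derived-copy estimates, variants are classified (common vs rare, fixed vs
polymorphic) and a copy-number-weighted site frequency spectrum is built:
the classical per-chromosome allele frequency is replaced by the summed
derived copies over the summed gene copies in the whole sample.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

POLARIZED = "polarized"
OUTGROUP_MISSING = "outgroup-missing"
OUTGROUP_THIRD_ALLELE = "outgroup-third-allele"


def polarize(variants: pd.DataFrame, outgroup: pd.DataFrame) -> pd.DataFrame:
    """Assign ancestral/derived states from an outgroup allele table.

    ``variants`` needs columns variant_id, ref, alt; ``outgroup`` needs
    variant_id, outgroup_allele.  The outgroup allele is taken as
    ancestral when it matches ref or alt; a third allele leaves the site
    unpolarized (excluded from the SFS), and absent outgroup data is
    flagged missing.
    """
    sites = variants.drop_duplicates("variant_id")[
        [c for c in ("variant_id", "gene", "pos", "ref", "alt") if c in variants.columns]
    ].copy()
    og = outgroup.set_index("variant_id")["outgroup_allele"]
    anc, der, status = [], [], []
    for _, row in sites.iterrows():
        allele = og.get(row.variant_id)
        if allele is None or (isinstance(allele, float) and np.isnan(allele)):
            anc.append(None); der.append(None); status.append(OUTGROUP_MISSING)
        elif allele == row.ref:
            anc.append(row.ref); der.append(row.alt); status.append(POLARIZED)
        elif allele == row.alt:
            anc.append(row.alt); der.append(row.ref); status.append(POLARIZED)
        else:
            anc.append(None); der.append(None); status.append(OUTGROUP_THIRD_ALLELE)
    sites["ancestral"] = anc
    sites["derived"] = der
    sites["status"] = status
    return sites


def variant_copies(gene_cn, ref_depth, alt_depth, derived_is_alt=True):
    """Copies bearing the derived allele: CN x derived reads / total reads.

    Vectorized; zero total depth yields NaN (missing), not zero.  When the
    reference allele is the derived one the complementary read fraction is
    used, so relabelling ref/alt with matching depths changes nothing.
    """
    gene_cn = np.asarray(gene_cn, dtype=float)
    ref_depth = np.asarray(ref_depth, dtype=float)
    alt_depth = np.asarray(alt_depth, dtype=float)
    total = ref_depth + alt_depth
    derived_reads = np.where(derived_is_alt, alt_depth, ref_depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, gene_cn * derived_reads / total, np.nan)
    return out if out.ndim else float(out)


def build_variant_copy_matrix(
    calls: pd.DataFrame,
    polarized: pd.DataFrame,
    cn_table: pd.DataFrame,
    cn_column: str = "total_cn",
) -> pd.DataFrame:
    """Long matrix of derived-copy estimates for every polarized variant.

    ``calls`` holds per-(variant, individual) allele depths; ``cn_table``
    must carry the individual's copy number for the variant's gene in
    ``cn_column`` (the *total* copies over both haplotypes for diploid
    chromosomes).  Unpolarized variants are dropped.
    """
    pol = polarized[polarized["status"] == POLARIZED]
    df = calls.merge(pol[["variant_id", "ancestral", "derived"]], on="variant_id")
    df = df.merge(cn_table[["individual", "gene", cn_column]].rename(
        columns={cn_column: "gene_cn"}), on=["individual", "gene"], how="left")
    df["derived_is_alt"] = df["derived"] == df["alt"]
    df["derived_copies"] = variant_copies(
        df["gene_cn"], df["ref_depth"], df["alt_depth"], df["derived_is_alt"].to_numpy())
    return df[["variant_id", "gene", "individual", "ref_depth", "alt_depth",
               "gene_cn", "derived_is_alt", "derived_copies"]]


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def classify_variants(
    matrix: pd.DataFrame,
    fixation_threshold: float = 0.95,
    common_min_copies: int = 2,
) -> pd.DataFrame:
    """Common/rare and fixed/polymorphic labels per variant.

    A variant is *common* when at least one individual carries it on at
    least ``common_min_copies`` copies (rounded half-up); *fixed* when the
    derived read fraction is >= ``fixation_threshold`` in every individual
    with data (a fixed difference from the outgroup); *singleton* when a
    single derived copy in a single individual is observed.
    """
    rows = []
    for vid, sub in matrix.groupby("variant_id", sort=False):
        has_data = sub["derived_copies"].notna()
        copies = sub.loc[has_data, "derived_copies"]
        cn = sub.loc[has_data, "gene_cn"]
        if not len(copies):
            rows.append((vid, False, "no-data", False))
            continue
        rounded = _round_half_up(copies)
        common = bool(rounded.max() >= common_min_copies)
        frac = copies.to_numpy() / cn.to_numpy()
        fixed = bool(np.all(frac >= fixation_threshold))
        singleton = bool(rounded.sum() == 1)
        rows.append((vid, common, "fixed" if fixed else "polymorphic", singleton))
    return pd.DataFrame(rows, columns=["variant_id", "common", "status", "singleton"])


def copy_weighted_sfs(
    matrix: pd.DataFrame,
    classes: pd.DataFrame,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Copy-number-weighted site frequency spectrum by variant class.

    Per-variant frequency = sum of derived copies over the whole sample /
    sum of the gene's copies over the whole sample, in [0, 1].  Counts go
    into left-closed bins with edges 0, 1/n, ..., 1; a frequency of
    exactly 1 lands in the top bin.  ``classes`` maps variant_id to
    var_class (e.g. NS/S).  Returns (per-variant frequencies, spectrum).
    """
    freq_rows = []
    for vid, sub in matrix.groupby("variant_id", sort=False):
        ok = sub["derived_copies"].notna()
        denom = sub.loc[ok, "gene_cn"].sum()
        num = sub.loc[ok, "derived_copies"].sum()
        freq_rows.append((vid, num / denom if denom > 0 else np.nan))
    freqs = pd.DataFrame(freq_rows, columns=["variant_id", "frequency"])
    freqs = freqs.merge(classes[["variant_id", "var_class"]], on="variant_id", how="left")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    valid = freqs.dropna(subset=["frequency"])
    bin_idx = np.minimum((valid["frequency"] * n_bins).astype(int), n_bins - 1)
    spectrum = (
        pd.DataFrame({"bin_left": edges[bin_idx], "var_class": valid["var_class"].to_numpy()})
        .value_counts().rename("count").reset_index()
        .pivot(index="bin_left", columns="var_class", values="count")
        .reindex(edges[:-1]).fillna(0).astype(int)
    )
    spectrum.index.name = "bin_left"
    return freqs, spectrum


# --- VCF interchange -------------------------------------------------------

def calls_to_vcf(calls: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write per-sample allele depths as a minimal multi-sample VCF (AD field)."""
    individuals = list(dict.fromkeys(calls["individual"]))
    sites = calls.drop_duplicates("variant_id")[["variant_id", "gene", "pos", "ref", "alt"]]
    by_site = calls.set_index(["variant_id", "individual"])
    contigs = list(dict.fromkeys(sites["gene"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(individuals) + "\n")
        for _, s in sites.iterrows():
            fields = [s.gene, str(int(s.pos)), s.variant_id, s.ref, s.alt, ".", ".", ".", "AD"]
            for ind in individuals:
                row = by_site.loc[(s.variant_id, ind)]
                fields.append(f"{int(row.ref_depth)},{int(row.alt_depth)}")
            fh.write("\t".join(fields) + "\n")


def read_vcf_calls(path: str | os.PathLike) -> pd.DataFrame:
    """Read a multi-sample VCF with per-sample AD into the long call table."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"{rec.id or rec.pos}: only biallelic SNVs are supported")
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            for sample, call in rec.samples.items():
                ad = call.get("AD")
                ref_d, alt_d = (ad[0] or 0, ad[1] or 0) if ad is not None else (0, 0)
                rows.append((vid, rec.chrom, rec.pos, rec.ref, rec.alts[0],
                             sample, int(ref_d), int(alt_d)))
    return pd.DataFrame(rows, columns=["variant_id", "gene", "pos", "ref", "alt",
                                       "individual", "ref_depth", "alt_depth"])
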