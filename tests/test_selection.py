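"""NS/S annotation and the McDonald-Kreitman / DoS / Fisher / FDR stack.

The per-gene 2x2 statistics are checked against the published per-gene
contingency counts for human sex-linked ampliconic genes, and against
independent brute-force oracles (codon translation table, hypergeometric
enumeration, direct BH step-up).
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplicnv.selection import (CDS, MKCounts, annotate_ns_s, bh_fdr, counts_from_classification,
                                direction_of_selection, fisher_exact_2x2, mk_alpha, mk_test,
                                pool_counts)

# Published polymorphic/fixed NS and S counts with their alpha, DoS and
# two-sided Fisher p for X- and Y-linked ampliconic genes.
PUBLISHED = [
    # gene,       Pn, Ps, Dn, Ds, alpha,  DoS,   p
    ("GAGE4",      7,  2,  4,  0,  1.00,  0.22, 1.00),
    ("CT47A4",    19,  7,  6,  3, -0.36, -0.06, 0.69),
    ("CT45A5",    10,  4,  4,  1,  0.38,  0.09, 1.00),
    ("SPANXB1",    6,  2,  2,  1, -0.50, -0.08, 1.00),
    ("BPY2",       3,  0,  2,  2,  None, -0.50, 0.429),
    ("CDY",       14,  6, 14,  7, -0.17, -0.03, 1.00),
    ("DAZ",        0,  0,  0,  0,  None,  None, 1.00),
    ("HSFY",       3,  1,  9,  1,  0.67,  0.15, 0.505),
    ("PRY",        0,  5,  6,  0,  1.00,  1.00, 2.16e-3),
    ("RBMY1A1",   23, 10, 20,  7,  0.20,  0.04, 0.779),
    ("XKRY",       0,  0,  0,  0,  None,  None, 1.00),
]


# --- independent oracles ---------------------------------------------------

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_ns_s(coding, idx, alt):
    codon_i = idx // 3
    c_ref = coding[3 * codon_i: 3 * codon_i + 3]
    c_alt = c_ref[: idx % 3] + alt + c_ref[idx % 3 + 1:]
    return "S" if CODON_TABLE[c_ref] == CODON_TABLE[c_alt] else "NS"


def oracle_fisher_two_sided(a, b, c, d):
    """Sum hypergeometric point masses <= the observed table's, fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = pmf(a)
    return sum(p for x in range(0, min(r1, c1) + 1)
               if (p := pmf(x)) <= p_obs * (1 + 1e-9))


def oracle_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


# --- tests -----------------------------------------------------------------

class TestAnnotation:
    def test_fourfold_site_synonymous(self):
        cds = CDS(exons=((0, 6),))
        assert annotate_ns_s(5, "A", "G", cds, "GGAGGA") == "S"  # GGA->GGG Gly

    def test_met_to_ile_nonsynonymous(self):
        cds = CDS(exons=((0, 3),))
        assert annotate_ns_s(2, "G", "A", cds, "ATG") == "NS"

    def test_stop_gain_is_nonsynonymous(self):
        cds = CDS(exons=((0, 3),))
        assert annotate_ns_s(1, "G", "A", cds, "TGG") == "NS"  # Trp -> stop

    def test_outside_cds_non_coding(self):
        cds = CDS(exons=((10, 16),))
        assert annotate_ns_s(2, "A", "G", cds, "A" * 20) == "non-coding"

    def test_indel_rejected(self):
        with pytest.raises(ValueError):
            annotate_ns_s(0, "AT", "A", CDS(exons=((0, 3),)), "ATG")

    def test_reverse_strand_uses_complement(self):
        # forward sequence CAT; reverse-complement coding strand reads ATG (Met)
        cds = CDS(exons=((0, 3),), strand="-")
        # pos 0 C->T makes forward TAT, rc ATA: Met -> Ile, nonsynonymous
        assert annotate_ns_s(0, "C", "T", cds, "CAT") == "NS"

    def test_random_snvs_match_translation_oracle(self, rng):
        bases = "ACGT"
        coding = "".join(rng.choice(list(bases), size=300))
        cds = CDS(exons=((50, 200), (250, 400)))
        seq = "".join(rng.choice(list(bases), size=50)) + coding[:150] \
            + "".join(rng.choice(list(bases), size=50)) + coding[150:] + "AAAA"
        for _ in range(100):
            pos = int(rng.choice(np.r_[50:200, 250:400]))
            ref = seq[pos]
            alt = rng.choice([b for b in bases if b != ref])
            idx = (pos - 50) if pos < 200 else (150 + pos - 250)
            assert annotate_ns_s(pos, ref, alt, cds, seq) == oracle_ns_s(coding, idx, alt)


class TestMKStatistics:
    @pytest.mark.parametrize("gene,pn,ps,dn,ds,alpha,dos,p", PUBLISHED)
    def test_published_contingency_tables(self, gene, pn, ps, dn, ds, alpha, dos, p):
        c = MKCounts(gene, pn, ps, dn, ds)
        if alpha is None:
            assert math.isnan(mk_alpha(c))
        else:
            assert abs(mk_alpha(c) - alpha) <= 0.005 + 1e-12
        if dos is None:
            assert math.isnan(direction_of_selection(c))
        else:
            assert abs(direction_of_selection(c) - dos) <= 0.005 + 1e-12
        # printed p-values carry 2-3 significant digits
        assert fisher_exact_2x2(c) == pytest.approx(p, rel=0.02)

    def test_zero_ds_with_positive_cells_gives_alpha_one(self):
        assert mk_alpha(MKCounts("g", 5, 3, 4, 0)) == 1.0

    def test_proportional_table_gives_dos_zero(self):
        assert direction_of_selection(MKCounts("g", 2, 1, 4, 2)) == pytest.approx(0.0)

    def test_symmetric_fisher_table(self):
        assert fisher_exact_2x2(MKCounts("g", 1, 1, 1, 1)) == pytest.approx(1.0)

    def test_extreme_table_p_is_hypergeometric_point_mass(self):
        # [[0, 5], [6, 0]]: the observed table is the most extreme one with
        # its margins, so p equals 1 / C(11, 5)
        assert fisher_exact_2x2(MKCounts("g", 0, 5, 6, 0)) == pytest.approx(1 / math.comb(11, 5))

    def test_random_tables_match_enumeration_oracle(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            got = fisher_exact_2x2(MKCounts("g", a, b, c, d))
            assert got == pytest.approx(oracle_fisher_two_sided(a, b, c, d), rel=1e-9)

    def test_pooling_additivity(self):
        counts = [MKCounts(g, pn, ps, dn, ds) for g, pn, ps, dn, ds, *_ in PUBLISHED]
        pooled = pool_counts(counts)
        assert (pooled.pn, pooled.ps, pooled.dn, pooled.ds) == (
            sum(c.pn for c in counts), sum(c.ps for c in counts),
            sum(c.dn for c in counts), sum(c.ds for c in counts))

    def test_pooled_chromosome_level_statistics(self):
        """Pooled X and Y counts reproduce the published chromosome-level values."""
        x = MKCounts("X", 223, 111, 114, 40)
        y = MKCounts("Y", 73, 42, 143, 59)
        # printed to two decimals; alpha(X) computes to 0.2951, printed 0.29
        assert abs(mk_alpha(x) - 0.29) <= 0.01
        assert round(direction_of_selection(x), 2) == pytest.approx(0.07)
        assert round(mk_alpha(y), 2) == pytest.approx(0.28)
        assert round(direction_of_selection(y), 3) == pytest.approx(0.073)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MKCounts("g", -1, 0, 0, 0)


class TestFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_all_equal(self):
        q = bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_random_vector_matches_step_up_oracle(self, rng):
        p = rng.uniform(0, 1, 20)
        assert np.allclose(bh_fdr(p), oracle_bh(p))

    def test_nan_passthrough_and_m_reduction(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m = 2, not 3
        assert np.allclose(q[[0, 2]], oracle_bh([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_qvalues_bounded_and_dominate_p(self, p):
        q = bh_fdr(p)
        assert np.all(q <= 1 + 1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)


def test_mk_test_batch_shape():
    counts = [MKCounts(g, pn, ps, dn, ds) for g, pn, ps, dn, ds, *_ in PUBLISHED[:4]]
    out = mk_test(counts)
    assert list(out["gene"]) == [c.gene_id for c in counts]
    assert out["fdr_q"].notna().all()


def test_counts_from_classification():
    classified = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3", "v4"],
        "status": ["polymorphic", "fixed", "fixed", "polymorphic"]})
    classes = pd.DataFrame({
        "variant_id": ["v1", "v2", "v3", "v4"],
        "gene": ["g", "g", "g", "g"],
        "var_class": ["NS", "NS", "S", "S"]})
    (c,) = counts_from_classification(classified, classes)
    assert (c.pn, c.ps, c.dn, c.ds) == (1, 1, 1, 1)
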