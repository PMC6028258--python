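"""V_ST, ANOVA, CN correlations and the median-variance comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from amplicnv.simulate import generate_truth
from amplicnv.structure import (anova_table, cn_anova, compare_distributions,
                                median_variance_profile, pairwise_cn_correlation,
                                vst, vst_table)

from conftest import small_config


def oracle_vst(groups, ddof=1):
    """Direct variance decomposition, written independently of the library."""
    allv = np.concatenate(groups)
    v_tot = allv.var(ddof=ddof)
    num = sum((g.var(ddof=ddof) if len(g) > ddof else 0.0) * len(g) for g in groups)
    v_within = num / sum(len(g) for g in groups)
    return (v_tot - v_within) / v_tot


def oracle_anova(groups):
    """Textbook between/within sum-of-squares F statistic."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(allv) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, stats.f.sf(f, df_b, df_w)


class TestVst:
    def test_zero_within_variance_gives_one(self):
        assert vst({"a": [1, 1, 1], "b": [5, 5, 5]}) == pytest.approx(1.0)

    def test_constant_values_are_degenerate(self):
        assert np.isnan(vst({"a": [3, 3], "b": [3, 3, 3]}))

    def test_matches_decomposition_oracle_on_random_partitions(self, rng):
        for _ in range(100):
            groups = [rng.normal(rng.uniform(0, 5), rng.uniform(0.5, 2),
                                 size=rng.integers(2, 20)) for _ in range(4)]
            assert vst(groups) == pytest.approx(oracle_vst(groups))

    def test_never_exceeds_one(self, rng):
        for _ in range(50):
            groups = [rng.normal(0, 1, rng.integers(2, 10)) for _ in range(3)]
            assert vst(groups) <= 1.0

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_affine_invariance(self, shift, scale):
        """Adding a constant or rescaling all CN values leaves V_ST unchanged."""
        rng = np.random.default_rng(8)
        groups = [rng.normal(3, 1, 12), rng.normal(5, 1, 9), rng.normal(4, 1, 15)]
        base = vst(groups)
        moved = vst([g * scale + shift for g in groups])
        assert moved == pytest.approx(base, rel=1e-9)

    def test_unweighted_option(self, rng):
        groups = [rng.normal(0, 1, 5), rng.normal(2, 3, 25)]
        allv = np.concatenate(groups)
        expect = (allv.var(ddof=1) - np.mean([g.var(ddof=1) for g in groups])) / allv.var(ddof=1)
        assert vst(groups, weighted=False) == pytest.approx(expect)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            vst({"a": [1, 2, 3]})

    def test_null_shift_is_centered_and_vst_grows_with_shift(self):
        """E[V_ST] ~ 0 with no population effect; increases with the shift."""
        rng = np.random.default_rng(9)
        means = {}
        for delta in (0.0, 1.0, 2.0):
            vals = []
            for _ in range(200):
                groups = [rng.normal(5 + delta * k, 1, 15) for k in range(3)]
                vals.append(vst(groups))
            means[delta] = np.mean(vals)
        assert abs(means[0.0]) < 0.03
        assert means[0.0] < means[1.0] < means[2.0]


class TestAnova:
    def test_equal_group_means_give_f_zero(self):
        f, p = cn_anova([np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_are_significant(self, rng):
        a = np.zeros(4) + rng.normal(0, 1e-3, 4)
        b = np.full(4, 10.0) + rng.normal(0, 1e-3, 4)
        _, p = cn_anova([a, b])
        assert p < 1e-3

    def test_matches_sum_of_squares_oracle(self, rng):
        for _ in range(50):
            groups = [rng.normal(rng.uniform(0, 3), 1, rng.integers(3, 15))
                      for _ in range(rng.integers(2, 5))]
            f, p = cn_anova(groups)
            f0, p0 = oracle_anova(groups)
            assert f == pytest.approx(f0)
            assert p == pytest.approx(p0)

    def test_two_group_f_equals_squared_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        f, _ = cn_anova([a, b])
        t, _ = stats.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2)

    def test_degenerate_layouts_give_nan(self):
        assert np.isnan(cn_anova([np.array([2.0, 2.0]), np.array([2.0])])[0])
        assert np.isnan(cn_anova([np.array([1.0])])[0])


class TestBatchTables:
    @pytest.fixture
    def cn_with_meta(self):
        cfg = small_config(seed=13)
        truth = generate_truth(cfg)
        cn = truth.cn.rename(columns={"true_cn": "cn"})[["individual", "gene", "cn"]]
        return cn, truth.meta

    def test_vst_table_per_gene(self, cn_with_meta):
        cn, meta = cn_with_meta
        out = vst_table(cn, meta, "population")
        assert set(out["gene"]) == {"geneL", "geneS"}
        assert (out["n_total"] == 15).all()

    def test_anova_table_has_fdr(self, cn_with_meta):
        cn, meta = cn_with_meta
        out = anova_table(cn, meta, "population")
        ok = out["p"].notna()
        assert (out.loc[ok, "q"] >= out.loc[ok, "p"] - 1e-12).all()

    def test_pairwise_correlation_of_identical_genes_is_one(self, cn_with_meta):
        cn, _ = cn_with_meta
        dup = cn[cn["gene"] == "geneL"].assign(gene="geneL_copy")
        out = pairwise_cn_correlation(pd.concat([cn, dup], ignore_index=True))
        row = out[(out["gene_a"] == "geneL") & (out["gene_b"] == "geneL_copy")]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_correlation_toy_table_matches_hand_computation(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 1, 4, 3, 6])
        cn = pd.DataFrame({
            "individual": list("vwxyz") * 2,
            "gene": ["A"] * 5 + ["B"] * 5,
            "cn": np.concatenate([a, b])})
        out = pairwise_cn_correlation(cn)
        r_hand = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert out["r"].iloc[0] == pytest.approx(r_hand)

    def test_null_correlations_controlled_by_fdr(self, rng):
        """Independent CN vectors: ~5% raw p < 0.05, ~none survive FDR."""
        n_ind, n_genes = 100, 10
        cn = pd.DataFrame({
            "individual": np.repeat([f"i{k}" for k in range(n_ind)], n_genes),
            "gene": np.tile([f"g{j}" for j in range(n_genes)], n_ind),
            "cn": rng.normal(5, 1, n_ind * n_genes)})
        out = pairwise_cn_correlation(cn)
        assert len(out) == 45
        raw_rate = (out["p"] < 0.05).mean()
        assert raw_rate < 0.15
        assert (out["q"] < 0.05).sum() == 0

    def test_constant_gene_gets_nan(self):
        cn = pd.DataFrame({"individual": list("abc") * 2,
                           "gene": ["A"] * 3 + ["B"] * 3,
                           "cn": [1.0, 1.0, 1.0, 1.0, 2.0, 3.0]})
        out = pairwise_cn_correlation(cn)
        assert np.isnan(out["r"].iloc[0])


class TestMedianVariance:
    def test_constant_cn_zero_variance(self):
        cn = pd.DataFrame({"individual": list("abcd"), "gene": "g", "cn": 3.0})
        out = median_variance_profile(cn)
        assert out["variance_cn"].iloc[0] == 0.0
        assert out["median_cn"].iloc[0] == 3.0

    def test_profile_matches_direct_computation(self, rng):
        vals = rng.uniform(1, 20, 30)
        cn = pd.DataFrame({"individual": [f"i{k}" for k in range(30)],
                           "gene": "g", "cn": vals})
        out = median_variance_profile(cn, class_map={"g": "Y"})
        assert out["median_cn"].iloc[0] == pytest.approx(np.median(vals))
        assert out["variance_cn"].iloc[0] == pytest.approx(vals.var(ddof=1))
        assert out["chrom_class"].iloc[0] == "Y"

    def test_rank_sum_detects_shifted_vst_distributions(self, rng):
        a = rng.uniform(0, 0.1, 15)
        b = a + 0.15
        u, p = compare_distributions(a, b)
        u0, p0 = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert (u, p) == (pytest.approx(u0), pytest.approx(p0))
        assert p < 0.01
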