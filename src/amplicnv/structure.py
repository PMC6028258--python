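"""Population structure of copy number: V_ST, ANOVA, correlations.

V_ST is the copy-number analogue of F_ST: with V_tot the variance of CN
over all individuals and V_i the variance within population i of size N_i,

    V_ST = (V_tot - sum_i V_i N_i / sum_i N_i) / V_tot

i.e. the fraction of copy-number variance explained by population
membership.  Sampling noise can push it slightly below zero; it never
exceeds 1.  A cut-off of 0.2 is conventionally used to flag substantial
between-population differentiation, and is reported here but never
asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .selection import bh_fdr

VST_DIFFERENTIATION_CUTOFF = 0.2


@dataclass
class VstResult:
    gene_id: str
    vst: float
    n_groups: int
    n_total: int


def _group_arrays(groups) -> list[np.ndarray]:
    if isinstance(groups, dict):
        groups = list(groups.values())
    return [np.asarray(g, dtype=float) for g in groups]


def vst(groups, ddof: int = 1, weighted: bool = True) -> float:
    """V_ST over groups of copy-number values.

    ``groups`` is a dict label -> values or a list of value arrays.  By
    default variances are sample variances (n-1 denominator) and the
    within-group term is the size-weighted mean of group variances
    (weights N_i / sum N_j); ``weighted=False`` uses the unweighted mean.
    Size-1 groups contribute zero within-group variance.  Returns NaN
    when total variance is zero.
    """
    arrays = _group_arrays(groups)
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise ValueError("V_ST needs >= 2 groups with >= 1 value each")
    values = np.concatenate(arrays)
    v_tot = np.var(values, ddof=ddof) if values.size > ddof else 0.0
    if v_tot == 0:
        return float("nan")
    v_i = np.array([np.var(a, ddof=ddof) if a.size > ddof else 0.0 for a in arrays])
    n_i = np.array([a.size for a in arrays], dtype=float)
    v_within = (v_i * n_i).sum() / n_i.sum() if weighted else v_i.mean()
    return float((v_tot - v_within) / v_tot)


def vst_table(
    cn_table: pd.DataFrame,
    metadata: pd.DataFrame,
    group_key: str = "population",
    ddof: int = 1,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-gene V_ST over the grouping in ``metadata[group_key]``."""
    df = cn_table.merge(metadata[["individual", group_key]], on="individual") \
        if group_key not in cn_table.columns else cn_table
    rows = []
    for gene, sub in df.groupby("gene", sort=False):
        sub = sub.dropna(subset=["cn"])
        groups = {k: g["cn"].to_numpy() for k, g in sub.groupby(group_key)}
        v = vst(groups, ddof=ddof, weighted=weighted) if len(groups) >= 2 else float("nan")
        rows.append((gene, v, len(groups), len(sub), bool(v > VST_DIFFERENTIATION_CUTOFF)))
    return pd.DataFrame(rows, columns=["gene", "vst", "n_groups", "n_total", "above_cutoff"])


def cn_anova(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F and p over copy-number groups.

    Degenerate layouts (all values identical, or fewer than two groups
    with data) return (NaN, NaN).
    """
    arrays = [a for a in _group_arrays(groups) if a.size > 0]
    if len(arrays) < 2 or sum(a.size for a in arrays) - len(arrays) < 1:
        return float("nan"), float("nan")
    if np.all(np.concatenate(arrays) == arrays[0][0]):
        return float("nan"), float("nan")
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def anova_table(
    cn_table: pd.DataFrame,
    metadata: pd.DataFrame,
    group_key: str = "population",
) -> pd.DataFrame:
    """Per-gene ANOVA of CN on a grouping factor, BH-corrected across genes."""
    df = cn_table.merge(metadata[["individual", group_key]], on="individual") \
        if group_key not in cn_table.columns else cn_table
    rows = []
    for gene, sub in df.groupby("gene", sort=False):
        sub = sub.dropna(subset=["cn"])
        groups = [g["cn"].to_numpy() for _, g in sub.groupby(group_key)]
        f, p = cn_anova(groups)
        rows.append((gene, f, p))
    out = pd.DataFrame(rows, columns=["gene", "F", "p"])
    out["q"] = bh_fdr(out["p"])
    return out


def pairwise_cn_correlation(cn_table: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Pearson correlation of CN between every gene pair, BH-corrected.

    Pairs with fewer than ``min_n`` shared individuals or a constant
    vector get NaN.  Correction spans the pairs actually tested.
    """
    wide = cn_table.pivot_table(index="individual", columns="gene", values="cn")
    rows = []
    for a, b in combinations(wide.columns, 2):
        sub = wide[[a, b]].dropna()
        if len(sub) < min_n or sub[a].nunique() == 1 or sub[b].nunique() == 1:
            rows.append((a, b, float("nan"), float("nan"), len(sub)))
            continue
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append((a, b, float(r), float(p), len(sub)))
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "n"])
    out["q"] = bh_fdr(out["p"])
    return out


def median_variance_profile(cn_table: pd.DataFrame, class_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-gene median and variance of CN (for the median-vs-variance view).

    ``class_map`` optionally labels each gene with its chromosome class
    (X / Y / autosome) for between-class comparison.
    """
    g = cn_table.groupby("gene")["cn"]
    out = g.agg(median_cn="median", variance_cn=lambda x: x.var(ddof=1), n="size").reset_index()
    out["chrom_class"] = out["gene"].map(class_map) if class_map else None
    return out


def compare_distributions(values_a, values_b) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) comparison of two value sets.

    Used e.g. to compare V_ST distributions between chromosome classes.
    Returns (U statistic, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
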