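"""Synthetic data generator for the whole pipeline.

Real input to this kind of study is whole-genome resequencing of a
population panel; what the downstream statistics actually consume is much
simpler, and this module generates exactly that with known ground truth:

* a reference region holding a tandem array of near-identical repeat-unit
  copies plus a unique single-copy control segment,
* per-individual per-base read depth, Poisson around (true copy number x
  per-copy depth) on units and (ploidy x per-copy depth) on the control,
* per-variant allele depths, binomial around the fraction of gene copies
  bearing the derived allele,
* an outgroup allele per variant site, and
* sample metadata (geographic region, haplogroup, sex).

Defaults emulate a male panel typed on Y-linked ampliconic genes: seven
geographic groups, per-copy depth 40 reads/base (median genome-wide
coverage of the emulated panel is ~42x), and four genes whose unit lengths
and median copy numbers follow well-known Y ampliconic families (a
TSPY-like short high-copy array through an XKRY-like two-copy gene).

All randomness flows from one master seed through named, deterministically
spawned streams, so identical configurations produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .depth import DepthProfile

_BASES = np.array(list("ACGT"))

# stream tags: keep fixed so each simulation stage is independently reproducible
_STREAM_TRUTH, _STREAM_REFERENCE, _STREAM_DEPTH, _STREAM_VARIANTS = 0, 1, 2, 3


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    size: int
    cn_shift: float = 0.0  # additive shift of the mean copy number in this group


@dataclass(frozen=True)
class GeneSpec:
    name: str
    unit_length: int
    base_cn: float = 3.0        # mean true copy number per chromosome
    cn_sd: float = 1.0          # between-individual SD of true copy number
    divergence: float = 0.001   # per-base divergence between repeat copies
    ref_copies: int | None = None  # copies in the simulated reference array

    def __post_init__(self):
        if self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")
        if not 0.0 <= self.divergence < 0.5:
            raise ValueError("per-copy divergence must be in [0, 0.5)")


@dataclass(frozen=True)
class VariantSpec:
    """One segregating or fixed variant within a gene's repeat unit.

    Either supply ``derived_copies`` explicitly (one integer per
    individual, clipped to that individual's copy number) or let the
    generator draw them: each individual is a carrier with probability
    ``carrier_freq`` and a carrier bears 1 + Binomial(CN - 1, copy_freq)
    derived copies.  ``copy_freq = 1`` with ``carrier_freq = 1`` yields a
    fixed difference against the ancestral state.
    """

    gene: str
    unit_pos: int               # 0-based position within the repeat unit
    var_class: str = "NS"       # "NS" or "S"
    carrier_freq: float = 1.0
    copy_freq: float = 0.5
    derived_copies: tuple | None = None
    derived_is_alt: bool | None = None  # None: drawn (reference usually ancestral)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("Africa", 24), PopulationSpec("America", 24),
        PopulationSpec("CentralAsiaSiberia", 24), PopulationSpec("EastAsia", 24),
        PopulationSpec("Oceania", 24), PopulationSpec("SouthAsia", 24),
        PopulationSpec("WestEurasia", 24),
    )
    genes: tuple[GeneSpec, ...] = (
        GeneSpec("TSPY_like", 6794, base_cn=23.0, cn_sd=5.0),
        GeneSpec("CDY_like", 16630, base_cn=3.0, cn_sd=0.8),
        GeneSpec("RBMY_like", 17098, base_cn=9.0, cn_sd=1.5),
        GeneSpec("XKRY_like", 5580, base_cn=2.0, cn_sd=0.5),
    )
    per_copy_depth: float = 40.0
    control_length: int = 10000
    variants: tuple[VariantSpec, ...] = ()
    outgroup_divergence: float = 0.01
    overdispersion: float = 0.0  # 0 = Poisson; >0 = gamma-Poisson mixing
    female_fraction: float = 0.0

    def __post_init__(self):
        if self.per_copy_depth <= 0:
            raise ValueError("per_copy_depth must be > 0")
        if any(p.size < 1 for p in self.populations):
            raise ValueError("population sizes must be >= 1")
        if not 0.0 <= self.outgroup_divergence <= 1.0:
            raise ValueError("outgroup_divergence must be in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return sum(p.size for p in self.populations)

    @property
    def individuals(self) -> list[str]:
        return [f"{p.label}_{i}" for p in self.populations for i in range(p.size)]


@dataclass
class SyntheticTruth:
    """Ground truth tables the estimators are judged against."""

    meta: pd.DataFrame           # individual, population, haplogroup, sex, ploidy
    cn: pd.DataFrame             # individual, gene, true_cn (per chromosome), total_cn
    variant_defs: pd.DataFrame   # variant_id, gene, unit_pos, var_class, alleles
    variant_copies: pd.DataFrame  # variant_id, individual, derived_copies


def _rng(config: SimulationConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *tags]))


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw true copy numbers, derived-copy counts, and sample labels."""
    rng = _rng(config, _STREAM_TRUTH)
    rows_meta, rows_cn = [], []
    for p_idx, pop in enumerate(config.populations):
        for i in range(pop.size):
            ind = f"{pop.label}_{i}"
            female = rng.random() < config.female_fraction
            ploidy = 2 if female else 1
            hap = f"H{p_idx * 2 + int(rng.random() < 0.3)}"
            rows_meta.append((ind, pop.label, hap, "F" if female else "M", ploidy))
            for gene in config.genes:
                per_hap = np.maximum(
                    1, np.rint(rng.normal(gene.base_cn + pop.cn_shift, gene.cn_sd, size=ploidy))
                ).astype(int)
                total = int(per_hap.sum())
                rows_cn.append((ind, gene.name, total / ploidy, total))
    meta = pd.DataFrame(rows_meta, columns=["individual", "population", "haplogroup", "sex", "ploidy"])
    cn = pd.DataFrame(rows_cn, columns=["individual", "gene", "true_cn", "total_cn"])

    gene_lengths = {g.name: g.unit_length for g in config.genes}
    total_by = cn.set_index(["individual", "gene"])["total_cn"]
    def_rows, copy_rows = [], []
    for v_idx, v in enumerate(config.variants):
        if v.gene not in gene_lengths:
            raise ValueError(f"variant references unknown gene {v.gene!r}")
        if not 0 <= v.unit_pos < gene_lengths[v.gene]:
            raise ValueError(f"variant position {v.unit_pos} outside unit of {v.gene!r}")
        anc, der = rng.choice(_BASES, size=2, replace=False)
        derived_is_alt = (rng.random() < 0.8) if v.derived_is_alt is None else v.derived_is_alt
        ref, alt = (anc, der) if derived_is_alt else (der, anc)
        vid = f"{v.gene}:{v.unit_pos + 1}"
        def_rows.append((vid, v.gene, v.unit_pos, v.var_class, anc, der, ref, alt, derived_is_alt))
        explicit = None if v.derived_copies is None else np.asarray(v.derived_copies)
        for j, ind in enumerate(config.individuals):
            cn_total = int(total_by[(ind, v.gene)])
            if explicit is not None:
                copies = int(min(explicit[j], cn_total))
            elif rng.random() < v.carrier_freq and cn_total > 0:
                copies = 1 + int(rng.binomial(cn_total - 1, v.copy_freq))
            else:
                copies = 0
            copy_rows.append((vid, ind, copies))
    variant_defs = pd.DataFrame(
        def_rows, columns=["variant_id", "gene", "unit_pos", "var_class",
                           "ancestral", "derived", "ref", "alt", "derived_is_alt"])
    variant_copies = pd.DataFrame(copy_rows, columns=["variant_id", "individual", "derived_copies"])
    return SyntheticTruth(meta, cn, variant_defs, variant_copies)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    for h in hits:
        choices = _BASES[_BASES != out[h]]
        out[h] = rng.choice(choices)
    return out


def simulate_reference(config: SimulationConfig):
    """Build synthetic source regions: tandem arrays plus a unique control.

    Returns (sequences, unit_intervals, control_interval) where sequences
    maps region names to strings, each unit interval is a BED-style tuple
    (region, start, end, gene_name) delimiting the first copy of the unit,
    and the control interval spans a unique segment with no repeats.
    """
    if config.control_length < 1:
        raise ValueError("control_length must be >= 1")
    rng = _rng(config, _STREAM_REFERENCE)
    sequences: dict[str, str] = {}
    unit_intervals: list[tuple[str, int, int, str]] = []
    for gene in config.genes:
        copies = gene.ref_copies if gene.ref_copies is not None else max(1, round(gene.base_cn))
        unit = rng.choice(_BASES, size=gene.unit_length)
        arr = [unit] + [_mutate(unit, gene.divergence, rng) for _ in range(copies - 1)]
        region = f"{gene.name}_region"
        sequences[region] = "".join("".join(c) for c in arr)
        unit_intervals.append((region, 0, gene.unit_length, gene.name))
    sequences["control_region"] = "".join(rng.choice(_BASES, size=config.control_length))
    control_interval = ("control_region", 0, config.control_length, "control")
    return sequences, unit_intervals, control_interval


def _depth_draw(lam: np.ndarray | float, size: int, od: float, rng: np.random.Generator) -> np.ndarray:
    if od > 0:
        lam = rng.gamma(shape=1.0 / od, scale=np.asarray(lam, dtype=float) * od, size=size)
        return rng.poisson(lam)
    return rng.poisson(lam, size=size)


def simulate_depth(truth: SyntheticTruth, config: SimulationConfig) -> dict[str, DepthProfile]:
    """Per-base depth per individual over every unit and the control.

    Unit bases are Poisson with mean total_CN x per-copy depth (total over
    both haplotypes for diploid chromosomes); control bases use ploidy x
    per-copy depth.  An ``overdispersion`` > 0 switches to a gamma-Poisson
    (negative binomial) mixture with variance lam(1 + od*lam).
    """
    lengths = {g.name: g.unit_length for g in config.genes}
    total_by = truth.cn.set_index(["individual", "gene"])["total_cn"]
    ploidy_by = truth.meta.set_index("individual")["ploidy"]
    profiles: dict[str, DepthProfile] = {}
    for idx, ind in enumerate(config.individuals):
        rng = _rng(config, _STREAM_DEPTH, idx)
        depths = {}
        for gene in config.genes:
            lam = float(total_by[(ind, gene.name)]) * config.per_copy_depth
            depths[gene.name] = _depth_draw(lam, lengths[gene.name], config.overdispersion, rng)
        lam_c = float(ploidy_by[ind]) * config.per_copy_depth
        depths["control"] = _depth_draw(lam_c, config.control_length, config.overdispersion, rng)
        profiles[ind] = DepthProfile(individual_id=ind, depths=depths, source="simulated")
    return profiles


def simulate_variant_calls(truth: SyntheticTruth, config: SimulationConfig):
    """Per-individual allele depths for each variant, plus outgroup alleles.

    At each variant site the read depth is Poisson(total_CN x per-copy
    depth) and the number of derived-allele reads is binomial with success
    probability derived_copies / total_CN, so ref_depth + alt_depth always
    equals the site depth.  The outgroup shows the ancestral allele except
    with probability ``outgroup_divergence``, where it mutates to one of
    the three other bases (possibly creating a third allele).
    """
    rng = _rng(config, _STREAM_VARIANTS)
    total_by = truth.cn.set_index(["individual", "gene"])["total_cn"]
    copies_by = truth.variant_copies.set_index(["variant_id", "individual"])["derived_copies"]
    rows = []
    for _, vd in truth.variant_defs.iterrows():
        for ind in config.individuals:
            cn_total = int(total_by[(ind, vd.gene)])
            copies = int(copies_by[(vd.variant_id, ind)])
            depth = int(rng.poisson(cn_total * config.per_copy_depth))
            frac = copies / cn_total if cn_total > 0 else 0.0
            derived_reads = int(rng.binomial(depth, frac))
            alt_depth = derived_reads if vd.derived_is_alt else depth - derived_reads
            rows.append((vd.variant_id, vd.gene, vd.unit_pos + 1, vd.ref, vd.alt,
                         ind, depth - alt_depth, alt_depth))
    calls = pd.DataFrame(rows, columns=["variant_id", "gene", "pos", "ref", "alt",
                                        "individual", "ref_depth", "alt_depth"])

    out_rows = []
    for _, vd in truth.variant_defs.iterrows():
        allele = vd.ancestral
        if rng.random() < config.outgroup_divergence:
            allele = rng.choice(_BASES[_BASES != vd.ancestral])
        out_rows.append((vd.variant_id, vd.gene, vd.unit_pos + 1, allele))
    outgroup = pd.DataFrame(out_rows, columns=["variant_id", "gene", "pos", "outgroup_allele"])
    return calls, outgroup


def default_variants() -> tuple[VariantSpec, ...]:
    """A study-like mix of segregating and fixed coding variants."""
    specs = []
    for gene, n_poly, n_fixed in [("TSPY_like", 4, 2), ("CDY_like", 5, 3),
                                  ("RBMY_like", 6, 3), ("XKRY_like", 2, 1)]:
        for i in range(n_poly):
            specs.append(VariantSpec(gene, 120 + 97 * i, var_class="NS" if i % 3 else "S",
                                     carrier_freq=0.35, copy_freq=0.4))
        for i in range(n_fixed):
            specs.append(VariantSpec(gene, 2000 + 211 * i, var_class="NS" if i % 2 else "S",
                                     carrier_freq=1.0, copy_freq=1.0))
    return tuple(specs)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The stock simulation: a male panel over four Y-like ampliconic genes."""
    cfg = SimulationConfig(seed=seed, variants=default_variants())
    return replace(cfg, **overrides) if overrides else cfg
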