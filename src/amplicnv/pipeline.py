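"""End-to-end orchestration of the synthetic demonstration pipeline.

Runs every stage in order on generated data with known truth: reference
simulation -> repeat discovery -> artificial reference -> depth ->
copy-number table -> variant polarization and per-variant copies ->
selection tests -> population structure -> distance tree.  All outputs
are plain text, written with a JSON manifest, and byte-identical across
reruns with the same configuration.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .copynumber import build_cn_table, cn_summary
from .io import write_bed, write_fasta, write_table
from .phylo import annotate_leaves, neighbor_joining, p_distance, write_tree
from .reference import build_reference
from .repeats import find_self_matches, infer_unit
from .selection import counts_from_classification, mk_test, pool_counts
from .simulate import (GeneSpec, PopulationSpec, SimulationConfig, VariantSpec,
                       default_config, generate_truth, simulate_depth,
                       simulate_reference, simulate_variant_calls)
from .structure import anova_table, median_variance_profile, pairwise_cn_correlation, vst_table
from .variants import (build_variant_copy_matrix, calls_to_vcf, classify_variants,
                       copy_weighted_sfs, polarize)
from .depth import write_depth_table

log = logging.getLogger("amplicnv")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    seed: int = 7
    outdir: str = "amplicnv_out"
    mapq_min: int = 50
    max_mismatches: int = 2
    fixation_threshold: float = 0.95
    common_min_copies: int = 2
    fdr_level: float = 0.05
    min_exact: int = 100
    step: int = 100
    simulation: dict = field(default_factory=dict)  # overrides for default_config

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        over = dict(self.simulation)
        if "populations" in over:
            over["populations"] = tuple(PopulationSpec(**p) for p in over["populations"])
        if "genes" in over:
            over["genes"] = tuple(GeneSpec(**g) for g in over["genes"])
        if "variants" in over:
            over["variants"] = tuple(VariantSpec(**v) for v in over["variants"])
        return default_config(seed=self.seed, **over)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate with failing stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic pipeline; returns the result bundle.

    Side effects: writes FASTA/BED/TSV/VCF/Newick artifacts plus
    ``manifest.json`` under ``config.outdir``.
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(outdir, name)
        write_table(df, path)
        artifacts[name] = path

    sim = config.simulation_config()
    truth = _stage("simulate-truth")(generate_truth)(sim)
    sequences, unit_ivs, control_iv = _stage("simulate-reference")(simulate_reference)(sim)

    @_stage("repeat-discovery")
    def discover():
        units = []
        for region, start, end, gene in unit_ivs:
            matches = find_self_matches(sequences[region], config.min_exact,
                                        config.step, include_reverse=False)
            units.append(infer_unit(matches, (region, 0, len(sequences[region])),
                                    gene_name=gene))
        return units
    units = discover()
    write_bed([(u.region_id, u.start, u.end, u.gene_name or u.region_id,
                u.copy_count_estimate) for u in units],
              os.path.join(outdir, "units.bed"))
    artifacts["units.bed"] = os.path.join(outdir, "units.bed")

    @_stage("build-reference")
    def buildref():
        return build_reference(units, control_iv, sequences)
    ref, records = buildref()
    write_fasta(records, os.path.join(outdir, "artificial_reference.fa"))
    artifacts["artificial_reference.fa"] = os.path.join(outdir, "artificial_reference.fa")
    save(ref.coordinate_table(), "coordinate_map.tsv")

    profiles = _stage("simulate-depth")(simulate_depth)(truth, sim)
    write_depth_table(profiles, os.path.join(outdir, "depth.tsv"))
    artifacts["depth.tsv"] = os.path.join(outdir, "depth.tsv")

    @_stage("copy-number")
    def copynum():
        table = build_cn_table(profiles, [g.name for g in sim.genes],
                               control="control", metadata=truth.meta)
        table["total_cn_est"] = table["cn"] * table["ploidy"]
        return table
    cn = copynum()
    save(cn, "cn_table.tsv")
    save(cn_summary(cn), "cn_summary.tsv")

    calls, outgroup = _stage("simulate-variants")(simulate_variant_calls)(truth, sim)
    save(calls, "variant_calls.tsv")
    save(outgroup, "outgroup_alleles.tsv")
    calls_to_vcf(calls, os.path.join(outdir, "variant_calls.vcf"))
    artifacts["variant_calls.vcf"] = os.path.join(outdir, "variant_calls.vcf")

    @_stage("variant-copies")
    def varcopies():
        pol = polarize(calls, outgroup)
        matrix = build_variant_copy_matrix(calls, pol, cn, cn_column="total_cn_est")
        return pol, matrix
    polarized, matrix = varcopies()
    save(polarized, "polarized_variants.tsv")
    save(matrix, "variant_copy_matrix.tsv")

    @_stage("selection")
    def select():
        classified = classify_variants(matrix, config.fixation_threshold,
                                       config.common_min_copies)
        counts = counts_from_classification(classified, truth.variant_defs)
        per_gene = mk_test(counts)
        pooled = mk_test([pool_counts(counts)], fdr=False)
        freqs, spectrum = copy_weighted_sfs(matrix, truth.variant_defs)
        return classified, per_gene, pooled, freqs, spectrum
    classified, mk_per_gene, mk_pooled, freqs, spectrum = select()
    save(classified, "variant_classification.tsv")
    save(mk_per_gene, "mk_results.tsv")
    save(mk_pooled, "mk_pooled.tsv")
    save(freqs, "variant_frequencies.tsv")
    save(spectrum.reset_index(), "sfs.tsv")

    @_stage("population-structure")
    def struct():
        return (vst_table(cn, truth.meta, "population"),
                anova_table(cn, truth.meta, "population"),
                anova_table(cn, truth.meta, "haplogroup"),
                pairwise_cn_correlation(cn),
                median_variance_profile(cn))
    vst_res, anova_region, anova_hap, corr, medvar = struct()
    save(vst_res, "vst.tsv")
    save(anova_region, "anova_region.tsv")
    save(anova_hap, "anova_haplogroup.tsv")
    save(corr, "cn_correlations.tsv")
    save(medvar, "median_variance.tsv")

    @_stage("distance-tree")
    def tree_stage():
        # haploid genotypes: derived allele carried (>= 1 estimated copy) or not
        geno = (matrix.assign(carrier=(matrix["derived_copies"].fillna(0) >= 0.5).astype(int))
                .pivot_table(index="individual", columns="variant_id", values="carrier"))
        dm = p_distance(geno)
        tree = neighbor_joining(dm)
        ann = annotate_leaves(tree, truth.meta[["individual", "population", "haplogroup"]])
        return tree, ann
    tree, ann = tree_stage()
    write_tree(tree, os.path.join(outdir, "nj_tree.nwk"), annotations=ann)
    artifacts["nj_tree.nwk"] = os.path.join(outdir, "nj_tree.nwk")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {k: getattr(config, k) for k in
                       ("mapq_min", "max_mismatches", "fixation_threshold",
                        "common_min_copies", "fdr_level", "min_exact", "step")},
        "artifacts": sorted(artifacts),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {"truth": truth, "units": units, "reference": ref, "cn_table": cn,
            "variant_copy_matrix": matrix, "classified": classified,
            "mk_results": mk_per_gene, "mk_pooled": mk_pooled, "sfs": spectrum,
            "vst": vst_res, "anova_region": anova_region, "anova_haplogroup": anova_hap,
            "correlations": corr, "tree": tree, "manifest": manifest}
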