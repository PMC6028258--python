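"""Estimate how many gene copies carry each derived allele, and build the
copy-number-weighted site frequency spectrum.

Variants called against the artificial reference aggregate all copies of a
gene: the derived-copy count per individual is gene CN x derived-read
fraction.  Because a classical per-chromosome SFS is impossible for
multicopy genes, derived frequency is summed derived copies / summed gene
copies over the whole sample.
"""

from amplicnv import generate_truth, simulate_variant_calls
from amplicnv.simulate import GeneSpec, PopulationSpec, SimulationConfig, VariantSpec
from amplicnv.variants import (build_variant_copy_matrix, classify_variants,
                               copy_weighted_sfs, polarize)

config = SimulationConfig(
    seed=2,
    populations=(PopulationSpec("pop", 30),),
    genes=(GeneSpec("CDY_like", 16630, base_cn=4.0, cn_sd=0.8),),
    variants=(VariantSpec("CDY_like", 120, "NS", carrier_freq=0.4, copy_freq=0.5),
              VariantSpec("CDY_like", 700, "S", carrier_freq=0.15, copy_freq=0.3),
              VariantSpec("CDY_like", 2500, "NS", carrier_freq=1.0, copy_freq=1.0)),
    outgroup_divergence=0.0,
)

truth = generate_truth(config)
calls, outgroup = simulate_variant_calls(truth, config)
polarized = polarize(calls, outgroup)
matrix = build_variant_copy_matrix(calls, polarized, truth.cn, cn_column="total_cn")
classes = classify_variants(matrix)
freqs, spectrum = copy_weighted_sfs(matrix, truth.variant_defs)

print(classes.to_string(index=False))
print()
print(freqs.round(3).to_string(index=False))
print("\nspectrum (left-closed decile bins):")
print(spectrum.to_string())
# The saturated variant is classified fixed with frequency 1.0; the two
# segregating variants are polymorphic with frequencies equal to their
# share of all gene copies in the sample.
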