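"""Discover the unit of repetition of a tandem array by exact self-matching.

Builds a region of five near-identical 3 kb copies (0.1% divergence),
finds maximal exact self-matches (>= 100 bp, the dotplot analogue), and
infers the repeat unit from the match offsets.
"""

from amplicnv import find_self_matches, infer_unit
from amplicnv.simulate import GeneSpec, SimulationConfig, simulate_reference

config = SimulationConfig(
    seed=4, genes=(GeneSpec("gene", 3000, divergence=0.001, ref_copies=5),))
sequences, _, _ = simulate_reference(config)
region = sequences["gene_region"]

matches = find_self_matches(region, min_exact=100, step=100, include_reverse=False)
unit = infer_unit(matches, ("gene_region", 0, len(region)))

print(f"region length      : {len(region)} bp")
print(f"self-matches >=100 : {len(matches)} (offsets are multiples of the unit)")
print(f"inferred unit      : {unit.length} bp")
print(f"estimated copies   : {unit.copy_count_estimate}")
# The offsets of off-diagonal self-matches are multiples of the repeat
# period, so the smallest offset recovers the generating 3000 bp unit and
# the number of distinct multiples counts the five copies.
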