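"""McDonald-Kreitman, direction-of-selection and Fisher tests.

Runs the selection statistics on published polymorphic/fixed NS and S
counts for human Y-linked ampliconic genes, per gene and pooled.
"""

from amplicnv import MKCounts, mk_test, pool_counts

counts = [
    MKCounts("BPY2", 3, 0, 2, 2),
    MKCounts("CDY", 14, 6, 14, 7),
    MKCounts("HSFY", 3, 1, 9, 1),
    MKCounts("PRY", 0, 5, 6, 0),
    MKCounts("RBMY1A1", 23, 10, 20, 7),
]

per_gene = mk_test(counts)
pooled = mk_test([pool_counts(counts)], fdr=False)

print(per_gene.round(3).to_string(index=False))
print()
print(pooled.round(3).to_string(index=False))
# alpha > 0 suggests an excess of nonsynonymous fixations (adaptive
# evolution), alpha < 0 segregating slightly deleterious variation; DoS
# carries the same sign logic but stays defined for sparse tables.  Only
# PRY's Fisher p is small here, and FDR across genes tempers even that.
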