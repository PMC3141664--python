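"""Agreement statistics on the packaged published replicate comparison.

The package ships the 9x9 cross-classification of 60,277 D. melanogaster
female-head exonic regions between two technical replicate lanes, binned on
the nine-level RPKM scale (0 = undetected, 1..8 = increasing expression).
"""

import techvar as tv

table = tv.load_reference_agreement_table()
collapsed = table.collapse_detection()

print(f"regions classified           : {table.n}")
print(f"simple agreement (9 levels)  : {tv.simple_agreement(table):.4f}")
print(f"detected in both lanes       : {collapsed.counts[1, 1]}")
print(
    "detected in exactly one lane : "
    f"{collapsed.counts[0, 1] + collapsed.counts[1, 0]}"
)
print(f"Cohen's kappa (detection)    : {tv.cohens_kappa(collapsed):.3f}")
print(f"weighted kappa (9 levels)    : {tv.weighted_kappa(table, 'linear'):.3f}")
print()
print("A weighted kappa of 0.80 despite a Spearman correlation near 0.95:")
print("correlation is not agreement - replicates can rank regions almost")
print("identically yet place many of them in different expression bins.")
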