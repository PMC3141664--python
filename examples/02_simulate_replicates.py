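"""Simulate two technical replicates as tiny samples of one molecule pool.

Builds the 20,000-gene library model (gamma(2,1) expression profile over
integer bins 0..17), draws two replicates of 300,000 reads each, and shows
how detection agreement depends on sequencing depth.
"""

import techvar as tv

library = tv.build_library(n_genes=20_000, seed=7)
print(f"realized pool size Z = {library.total_molecules:.4g} molecules")
print(f"genes with zero molecules: {(library.molecule_counts == 0).sum()}")

for n_reads in (300_000, 3_000_000):
    rep1, rep2 = tv.simulate_experiment(library, 2, n_reads, base_seed=8)
    table, n_common, n_only_one = tv.detection_comparison(
        rep1.read_counts > 0, rep2.read_counts > 0
    )
    kappa = tv.cohens_kappa(table)
    print(
        f"n_reads={n_reads:>9,}: detected in both={n_common}, "
        f"in exactly one={n_only_one}, detection kappa={kappa:.3f}"
    )

print()
print("Even though both lanes sample the SAME pool, over a thousand genes")
print("are seen in only one of them.  Deeper sequencing detects far more")
print("genes in both lanes, but the detection boundary just shifts to ever")
print("rarer transcripts, so some discordance persists at any depth.")
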