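"""Fst/Rst distances between diverged populations, MDS and an NJ tree."""

import numpy as np

from strpopgen import (
    classical_mds,
    neighbor_joining,
    nearest_populations,
    pairwise_fst,
    sample_allele_frequencies,
    simulate_diverged_populations,
    to_newick,
)

rng = np.random.default_rng(4)
ancestral = {
    f"L{i:02d}": dict(zip((str(8 + j) for j in range(6)),
                          sample_allele_frequencies(6, 1.5, rng)))
    for i in range(15)
}
pops, truth = simulate_diverged_populations(
    ancestral, f_div=0.05, n_per_pop=300, n_pops=5, seed=rng
)

fst = pairwise_fst(pops)
print("pairwise Weir-Cockerham theta (generating Fst = 0.05):")
print(fst.to_frame().round(4).to_string())

print("\nclosest to POP1:", nearest_populations(fst, "POP1", k=2))

mds = classical_mds(fst, dims=2)
print("\nMDS coordinates (first positive axes):")
print(mds.to_frame().round(4).to_string())

print("\nNJ tree:", to_newick(neighbor_joining(fst)))
# Populations drawn independently from the same ancestral pool are roughly
# equidistant (theta near 2x the single-population divergence), so the MDS
# cloud is spread and the NJ tree is star-like.
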