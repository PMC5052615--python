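"""Community ecology: Shannon diversity, Bray-Curtis and PCoA.

Aggregates gene abundances to species level via best-hit taxonomy,
computes per-sample alpha diversity, and ordinates samples by classical
scaling of the Bray-Curtis dissimilarity matrix.
"""

from mgskit import (
    SimulationConfig,
    aggregate_by_taxon,
    bray_curtis,
    gene_relative_abundance,
    pcoa,
    rank_sum_test,
    shannon_index,
    simulate_dataset,
)

ds = simulate_dataset(SimulationConfig(seed=5))
abund = gene_relative_abundance(ds.counts, ds.genes)
species = aggregate_by_taxon(abund, ds.hits, rank="species")

g_a, g_b = ds.labels.two_groups()
shannon = {s: shannon_index(species.values[s]) for s in species.sample_ids}
h_a = [shannon[s] for s in ds.labels.samples_of(g_a)]
h_b = [shannon[s] for s in ds.labels.samples_of(g_b)]
p, _ = rank_sum_test(h_a, h_b)
print(f"Shannon (species level): {g_a} mean {sum(h_a)/len(h_a):.3f}, "
      f"{g_b} mean {sum(h_b)/len(h_b):.3f} (rank-sum p = {p:.3f})")

ordination = pcoa(bray_curtis(species), n_axes=2)
pc1, pc2 = ordination.proportion_explained[:2]
print(f"PCoA of Bray-Curtis distances: axis 1 explains {pc1:.1%}, "
      f"axis 2 {pc2:.1%} of the positive-eigenvalue variance")
print(ordination.coordinates.head())
# The planted cohort shifts separate the two groups along the leading
# axes; diversity differs only through compositional side-effects.
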