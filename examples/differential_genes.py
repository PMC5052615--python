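"""Two-group differential gene abundance with Wilcoxon + BH.

Builds gene-level relative abundances (read-pair counts normalised by
gene length), tests every gene between the two cohorts, and reports the
counts each cohort is enriched for — the gene-marker step that feeds
MGS clustering.
"""

from mgskit import (
    SimulationConfig,
    differential_features,
    gene_relative_abundance,
    simulate_dataset,
)

ds = simulate_dataset(SimulationConfig(seed=7))
abund = gene_relative_abundance(ds.counts, ds.genes)
diff = differential_features(abund, ds.labels, q_threshold=0.001)

sig = diff[diff["significant"]]
print(f"tested {len(diff)} genes, {len(sig)} significant at q < 0.001")
for group, count in sig["direction"].value_counts().items():
    print(f"  enriched in {group}: {count} genes")
print("most significant gene:", sig["q_value"].idxmin(),
      f"(q = {sig['q_value'].min():.2e})")
# Genes of the three planted differential species dominate the
# significant set; the direction says which cohort carries more of them.
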