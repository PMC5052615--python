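# mgskit

Gene-level comparative metagenomics for two-cohort shotgun studies —
the analysis chain used to compare gut microbiomes between populations
via a reference gene catalogue:

1. **Profiling** — mapped read-pair counts `x_g` become length-normalised
   relative abundances `a_g = (x_g / L_g) / Σ_j (x_j / L_j)` per sample,
   and are accumulated to KO/OG terms or taxonomic ranks.
2. **Differential genes** — per-gene two-sided Wilcoxon rank-sum tests
   between cohorts (exact by enumeration for small groups, normal
   approximation with tie/continuity correction otherwise), adjusted by
   Benjamini–Hochberg step-up; genes called at *q* < 0.001.
3. **Metagenomic species (MGS)** — differential genes clustered at
   Spearman ρ > 0.8 by single linkage (connected components of the
   thresholded correlation graph), large clusters (> 25 genes) fused
   while their median profiles stay correlated above 0.8; each MGS gets
   25 *tracer* genes, a per-sample median abundance profile, a consensus
   taxon (deepest rank whose name covers > 90 % of member genes among
   best hits with > 95 % identity and > 90 % overlap), and membership in
   a co-occurrence network linking MGS at ρ > 0.6.
4. **Reporter scores** — per-KO signed Z-scores `z = Φ⁻¹(1 − p/2)` are
   aggregated per KEGG module as `Z_raw = Σz/√k` and standardised
   against random size-*k* KO sets; modules with reporter score > 1.6
   (either direction) are called differentially enriched.
5. **Community ecology** — Shannon index, richness, Bray–Curtis
   dissimilarity and classical-scaling PCoA.
6. **Diet associations** — pairwise-complete Spearman ρ between MGS
   profiles and nutrient variables, flagged `+` (*P* < 0.05) and `*`
   (*P* < 0.01).

A synthetic two-cohort generator (`mgskit.simulate`) plants known
species→gene structure, differential species, enriched modules and
nutrient couplings, so the whole chain can be validated by recovery of
a known truth — useful for method development, power checks, and as a
test bed when the real read data are out of reach.

## Worked example

```python
from mgskit import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(seed=1, out_dir="run", simulation=SimulationConfig(seed=1))
res = run_pipeline(cfg)
```

(or `python examples/simulate_and_recover.py`), which prints:

```
significant genes (q < 0.001): 300
  MGS001: 100 genes, taxon 'Species001 strain T' (strain), enriched in Mongolian
  MGS002: 100 genes, taxon 'Species002 strain T' (strain), enriched in Mongolian
  MGS003: 100 genes, taxon 'Species003 strain T' (strain), enriched in Han
recovery vs planted truth:
  ari: 1.000
  species_direction_accuracy: 1.000
  module_recall: 1.000
  diet_flagged_fraction: 1.000
```

All 300 genes of the three planted 2-log2-fold shifted species are
detected, cluster into exactly three MGS matching the planted species
partition (adjusted Rand index 1.0), each MGS is flagged enriched in
the cohort its species was shifted towards, both planted KO modules are
recovered with the right direction, and both planted nutrient couplings
surface as significant correlations. The run directory contains every
stage's TSV output (`diff.tsv`, `mgs/`, `network.graphml`,
`reporter.tsv`, `pcoa.tsv`, `corr.tsv`, `recovery.tsv`) plus a
`manifest.json` recording all parameters and seeds; rerunning the same
config reproduces it byte for byte.

There is also a thin CLI (`mgskit simulate|profile|aggregate|diff|
community|diet|run-all`) over the same functions, and one short script
per capability under `examples/`.

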