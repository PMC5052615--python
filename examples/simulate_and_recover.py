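"""End-to-end run: simulate a two-cohort metagenome, recover the truth.

Generates the default synthetic study (20 species x 100 genes, 30+30
samples, three species shifted 2 log2-fold between cohorts, two KO
modules riding on them, two nutrients rank-coupled to species), runs
every pipeline stage, and scores the result against the planted truth.
"""

from mgskit import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    seed=1, out_dir="scratch/example_run", simulation=SimulationConfig(seed=1)
)
res = run_pipeline(cfg)

print(f"significant genes (q < 0.001): {int(res['diff']['significant'].sum())}")
for b in res["mgs_bins"]:
    print(
        f"  {b.mgs_id}: {b.size} genes, taxon {b.taxon!r} ({b.taxon_rank}), "
        f"enriched in {b.enriched_in}"
    )
print("recovery vs planted truth:")
for k, v in res["recovery"].items():
    print(f"  {k}: {v:.3f}")
# ari = 1.0 means every clustered gene landed in the MGS of its true
# species; direction accuracy 1.0 means each shifted species' MGS was
# flagged enriched in the cohort it was planted in.
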