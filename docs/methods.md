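# Methods

This note documents the statistical models behind `mgskit`, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions.

## Gene abundance model

Read pairs are counted per catalogue gene only when both mates map to
the same gene, so counts are whole pairs. Relative abundance divides
each gene's count by its length before normalising the sample to 1:
`a_g = (x_g / L_g) / Σ_j (x_j / L_j)`. Length normalisation removes the
bias that longer ORFs collect more pairs; it is exercised end-to-end by
the generator, which draws counts with probability proportional to
abundance × length. Columns of a relative matrix must sum to 1 within
1e-9; all-zero samples are rejected by name.

Aggregation to KO/OG terms sums member-gene abundances. A gene
annotated to several terms contributes its **full** abundance to each —
deliberate double counting that keeps each term's profile independent
of other terms' membership; `split_multi=True` divides instead.
Taxon aggregation keeps an `unclassified` bucket by default so species
columns still sum to 1; hits qualify only at identity strictly > 95 and
overlap strictly > 90 (per cent).

## Differential testing

Two-sided Wilcoxon rank-sum per feature. Exact mode enumerates all
C(n+m, n) assignments of the pooled average ranks to one group and
counts assignments at least as far from the null mean rank sum — this
handles ties exactly and is used automatically when min(n, m) ≤ 8 and
the pooled values are tie-free (it can be forced with
`method="exact"`, ties included). Otherwise the normal approximation
with tie and continuity correction is used (vectorised across features
for two-group matrices). Direction is the group with the higher mean
rank; identical rank sums give `"tie"`.

BH adjustment is the step-up `q_(i) = min_{j≥i} p_(j)·m/j`, capped at
1, returned in input order. Features that are zero in **every** sample
are untestable and are dropped before `m` is counted (logged); they
would otherwise dilute the correction. Note the step-up map is not
idempotent — applying it to its own output can inflate values — so
q-values are computed from p-values only, once.

## MGS clustering

Differential genes are correlated by Spearman ρ (average ranks) across
**all** samples, both cohorts pooled. Single-linkage clustering cut at
similarity ρ > 0.8 equals the connected components of the graph with an
edge wherever ρ > 0.8; the component formulation removes any dendrogram
ambiguity and is O(E). Clusters of more than 25 genes are then fused
greedily: the pair whose **representative profiles** (per-sample median
over member genes) correlate most strongly is merged, the
representative recomputed, and the loop repeats while the best pair
exceeds ρ = 0.8, ties breaking towards the lexicographically smaller
pair. Comparing representatives rather than all cross-cluster gene
pairs follows the canopy-profile tradition of co-abundance binning and
is robust to single noisy genes. Clusters that never exceed 25 genes
are retained in a side table but never reported as MGS.

Each MGS keeps the 25 member genes with the highest ρ to the cluster
median as tracers (ties: higher mean abundance, then gene id), and its
abundance profile is the per-sample median of the tracers (configurable
to all members). `enriched_in` is the majority differential direction
of the member genes. Consensus taxonomy walks ranks from strain up to
superkingdom and assigns the deepest rank at which one name accounts
for more than 90 % of **all** member genes (genes with no qualifying
hit count against the consensus; a lenient mode restricts the
denominator to qualifying genes). The co-occurrence network links MGS
whose profiles correlate at ρ strictly > 0.6, with mean relative
abundance and an order-level taxon as node attributes.

Strict thresholds are compared with a 1e-9 epsilon, so a pair whose
exact rank correlation equals the threshold (floating-point value
0.6000000000000001) is treated as *at* the threshold and not linked.

## Reporter scores

Each KO's two-sided rank-sum p becomes a signed Z-score
`z = ±Φ⁻¹(1 − p/2)`, positive when the KO ranks higher in the focal
group; p is clipped to [1e-15, 1 − 1e-15] before inversion, and
constant KOs score 0 with a warning. A module's raw score is
`Z_raw = Σ_{i∈module} z_i / √k` over its k scored member KOs. The
background draws `n_background = 1000` random size-k sets **from the
scored KO universe** (not the full ontology — this keeps the null
exchangeable with the observed module) and standardises:
`Z_reporter = (Z_raw − μ_k) / σ_k`. Because negating every z flips μ_k
and leaves σ_k unchanged, the score of the mirrored run is exactly
−Z_reporter; both directions are therefore evaluated from one
computation, and a module is enriched towards the focal group when
Z_reporter > 1.6 or towards the other group when −Z_reporter > 1.6.
A module covering the whole universe has σ_k = 0 and raises an error.
The background seed is recorded in the output header.

## Community ecology

Shannon `H = −Σ p ln p` on the renormalised non-zero profile (natural
log; base-2 by flag), richness as features strictly above a detection
threshold, Bray–Curtis `Σ|x−y| / Σ(x+y)`, and PCoA by classical
scaling: double-centre −½ J D² J, eigendecompose, coordinates =
eigenvector · √λ for positive eigenvalues in descending order. Negative
eigenvalues (Bray–Curtis is generally non-Euclidean) are reported, not
corrected — no Lingoes/Cailliez adjustment, for transparency. Axis
signs are fixed so each axis's largest-magnitude coordinate is
positive, making ordinations reproducible.

## Diet associations

Pairwise-complete Spearman ρ per (MGS, nutrient) with two-sided p from
the t-approximation `t = ρ√((n−2)/(1−ρ²))` on n − 2 df — standard at
cohort sizes of tens to hundreds; a seeded permutation mode exists for
small n. Cells with fewer than 5 complete pairs are reported missing
with a reason. Flags follow the raw-p convention (`+` for P < 0.05,
`*` for P < 0.01); a BH-adjusted column is emitted alongside as a
clearly-labelled extra, since the flag convention itself applies no
multiplicity correction.

## Synthetic generator

The generator emulates exactly the statistical structure the methods
assume, at desk scale:

- **Species trajectories**: per species, a fixed base level
  `exp(N(0, 0.6))` times per-sample log-normal variation
  `exp(N(0, 0.6))`. Differential species are multiplied by `2^effect`
  in their target group (default three species at ±2 log2).
- **Genes**: gene abundance = species trajectory × a fixed per-gene
  factor `exp(N(0, 0.5))` (a copy-number/mappability surrogate drawn
  once, so genes differ in level but co-vary) × multiplicative noise
  `exp(N(0, gene_noise_sigma))`, default σ = 0.3.
- **Counts**: multinomial thinning of length-weighted abundance at a
  fixed per-sample depth (default 200,000 pairs), so column sums equal
  the depth exactly and length normalisation is genuinely exercised.
  Gene lengths are log-normal with median ≈ 750 bp, floored at the
  100 bp ORF threshold.
- **Taxonomy**: every gene carries its species' strain-level lineage at
  qualifying identity/overlap, except a `contamination_rate` fraction
  (default 2 %) given a wrong species' lineage.
- **Modules**: each planted module's KOs are attached to genes of
  differential species shifted towards the same group (3 carrier genes
  per KO), and those carrier genes get an extra `2^shift` fold in the
  target group; null modules are random subsets of the background KOs
  ordinary genes draw from. Config validation requires a matching
  differential species for every planted module.
- **Nutrients**: a Gaussian copula on the species profile's normal
  scores, with latent correlation `r = 2 sin(πρ/6)` so the **Spearman**
  correlation hits the configured target ρ; uncoupled nutrients are
  independent noise.

The three spread parameters (0.6 between species, 0.6 across samples,
0.5 between genes) are set so that the planted 2-log2 effect is a
≈ 2.3-SD shift on the log scale — strongly detectable at 30 + 30
samples without being degenerate — while within-species rank
correlation stays safely above the 0.8 clustering threshold and every
gene keeps enough read pairs to be testable. Everything is driven by
one integer seed through a single `numpy` Generator; identical configs
produce byte-identical output directories.

What the generator does **not** emulate: zero inflation beyond
multinomial sampling, strain mixtures within a species, correlated
noise between species (beyond compositional closure), phylogenetically
structured effect sizes, uneven sequencing depth, chimeric or
mis-assembled genes, and annotation errors other than lineage
contamination. Passing recovery tests therefore demonstrate
correctness of the inference chain under its own assumptions, not
performance on real stool metagenomes, where cluster fragmentation and
taxonomic ambiguity are substantially worse.

## Problem sizes and reproducibility

The default test-bed is 20 species × 100 genes and 30 + 30 samples at
200,000 pairs/sample — small enough that the full pipeline runs in a
few seconds while every stage sees realistic data shapes. The
validation suite checks exact-test enumeration against exhaustive
permutation (groups ≤ 6), BH against the quadratic definition (1,000
random vectors), null false-positive control at 5,000 genes × 20
label permutations, planted-structure recovery over seeds 1–5 (ARI,
direction, modules, nutrients), and byte-identical reruns.
`scripts/acceptance.py` recomputes the same quantities from scratch at
any seed.

## Known limitations

- The fusion step is O(k²) in eligible clusters per iteration — fine
  for tens of MGS, not tuned for thousands.
- The exact Wilcoxon path enumerates combinations and is only intended
  for min(n, m) ≤ 8.
- Reporter backgrounds are Monte-Carlo (n = 1000); scores near the 1.6
  threshold carry ≈ 0.03 standardisation noise.
- `diet_correlation` tests each cell independently; the flag convention
  is raw-p by design, so expect ≈ 5 % flagged cells under a global null.
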