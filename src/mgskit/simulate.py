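"""Two-cohort synthetic gene-level metagenomes with planted ground truth.

The generator emulates the statistical structure the downstream methods
assume: genes of one species share that species' abundance trajectory
across samples (up to a fixed per-gene factor and multiplicative
log-normal noise), some species are shifted between cohorts by a known
log2 effect, selected KO modules ride on genes of those shifted
species, and selected nutrients are rank-coupled to species profiles at
a target Spearman rho via a Gaussian copula.  Read-pair counts come
from multinomial thinning of length-weighted abundances at a fixed
per-sample depth, so the length-normalisation step is exercised.

Everything is driven by one integer seed; the same config yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AbundanceMatrix,
    AnnotationMap,
    CohortLabels,
    CountMatrix,
    GeneHits,
    GeneTable,
    NutrientTable,
    format_lineage,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_dataset",
    "truth_recovery_report",
    "write_run_dir",
]

DEFAULT_NUTRIENTS = ("protein", "K", "Zn", "Fe", "VB1", "Se", "Mg")


@dataclass
class SimulationConfig:
    """Knobs of the two-cohort generator; the defaults are the study
    conditions used throughout the test-bed.

    ``differential_species`` entries are (species id, target group,
    log2 effect); ``enriched_modules`` are (module id, target group,
    per-KO log2 shift applied to the module's carrier genes);
    ``diet_correlated`` are (species id, nutrient id, target Spearman
    rho).
    """

    seed: int
    n_species: int = 20
    genes_per_species: int | list[int] = 100
    n_samples_per_group: tuple[int, int] = (30, 30)
    group_names: tuple[str, str] = ("Mongolian", "Han")
    gene_noise_sigma: float = 0.3
    species_lognormal_mu_sigma: tuple[float, float] = (0.0, 0.6)
    species_base_sigma: float = 0.6  # between-species spread of mean levels
    gene_factor_sigma: float = 0.5  # spread of the fixed per-gene level factor
    differential_species: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("sp001", "Mongolian", 2.0),
            ("sp002", "Mongolian", 2.0),
            ("sp003", "Han", 2.0),
        ]
    )
    enriched_modules: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("M0001", "Mongolian", 1.0), ("M0002", "Han", 1.0)]
    )
    module_size: int = 8
    n_null_modules: int = 4
    carriers_per_ko: int = 3
    diet_correlated: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("sp001", "protein", 0.6), ("sp002", "Se", 0.6)]
    )
    nutrient_ids: tuple[str, ...] = DEFAULT_NUTRIENTS
    contamination_rate: float = 0.02
    depth: int = 200_000
    n_ko: int = 200
    annotation_rate: float = 0.7

    def species_ids(self) -> list[str]:
        return [f"sp{i + 1:03d}" for i in range(self.n_species)]

    def genes_of(self) -> dict[str, list[str]]:
        per = (
            [self.genes_per_species] * self.n_species
            if isinstance(self.genes_per_species, int)
            else list(self.genes_per_species)
        )
        if len(per) != self.n_species:
            raise ValueError("genes_per_species list length != n_species")
        return {
            sp: [f"{sp}.g{k + 1:03d}" for k in range(n)]
            for sp, n in zip(self.species_ids(), per)
        }

    def validate(self) -> None:
        if self.n_species < 1 or min(self.n_samples_per_group) < 1:
            raise ValueError("all counts must be >= 1")
        per = self.genes_of()
        if any(len(g) < 1 for g in per.values()):
            raise ValueError("each species needs at least 1 gene")
        if not 0 <= self.contamination_rate <= 1:
            raise ValueError("contamination_rate must be in [0, 1]")
        if self.gene_noise_sigma < 0:
            raise ValueError("gene_noise_sigma must be >= 0")
        valid_sp = set(self.species_ids())
        valid_groups = set(self.group_names)
        for sp, grp, eff in self.differential_species:
            if sp not in valid_sp or grp not in valid_groups or not np.isfinite(eff):
                raise ValueError(f"bad differential_species entry ({sp}, {grp}, {eff})")
        for sp, nut, rho in self.diet_correlated:
            if abs(rho) > 1:
                raise ValueError(f"infeasible target rho {rho} for ({sp}, {nut})")
            if sp not in valid_sp or nut not in self.nutrient_ids:
                raise ValueError(f"bad diet_correlated entry ({sp}, {nut}, {rho})")
        diff_dirs = {grp for _, grp, _ in self.differential_species}
        for mod, grp, shift in self.enriched_modules:
            if grp not in valid_groups or not np.isfinite(shift):
                raise ValueError(f"bad enriched_modules entry ({mod}, {grp}, {shift})")
            if grp not in diff_dirs:
                raise ValueError(
                    f"module {mod} targets {grp!r} but no differential species "
                    "is planted towards that group to carry it"
                )


@dataclass
class SyntheticTruth:
    """Planted structure: what a perfect analysis should recover."""

    species_genes: dict[str, list[str]]
    species_lineage: dict[str, str]
    differential_species: list[tuple[str, str, float]]
    enriched_modules: list[tuple[str, str, float]]
    diet_correlated: list[tuple[str, str, float]]


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    genes: GeneTable
    labels: CohortLabels
    hits: GeneHits
    annotations: AnnotationMap
    nutrients: NutrientTable
    truth: SyntheticTruth
    true_abundance: AbundanceMatrix  # noise-level gene abundance before counting
    species_abundance: pd.DataFrame  # latent species trajectories (absolute scale)


def _species_lineages(species_ids: list[str]) -> dict[str, dict[str, str]]:
    """Nested synthetic taxonomy: pairs of species share a genus, and so on."""
    out = {}
    for i, sp in enumerate(species_ids):
        out[sp] = {
            "superkingdom": "Bacteria",
            "phylum": f"Phylum{i // 32 + 1:02d}",
            "class": f"Class{i // 16 + 1:02d}",
            "order": f"Order{i // 8 + 1:02d}",
            "family": f"Family{i // 4 + 1:02d}",
            "genus": f"Genus{i // 2 + 1:02d}",
            "species": f"Species{i + 1:03d}",
            "strain": f"Species{i + 1:03d} strain T",
        }
    return out


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate one two-cohort dataset plus its ground-truth record."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    species = cfg.species_ids()
    species_genes = cfg.genes_of()
    gene_ids = [g for sp in species for g in species_genes[sp]]
    gene_species = {g: sp for sp in species for g in species_genes[sp]}
    n_a, n_b = cfg.n_samples_per_group
    g_a, g_b = cfg.group_names
    sample_ids = [f"{g_a}_{j + 1:02d}" for j in range(n_a)] + [
        f"{g_b}_{j + 1:02d}" for j in range(n_b)
    ]
    groups = [g_a] * n_a + [g_b] * n_b
    n_samples = n_a + n_b

    # --- species abundance: log-normal across samples, per-species base level
    mu, sigma = cfg.species_lognormal_mu_sigma
    base = np.exp(rng.normal(mu, cfg.species_base_sigma, size=len(species)))
    log_a = rng.normal(0.0, sigma, size=(len(species), n_samples))
    species_abund = base[:, None] * np.exp(log_a)
    for sp, grp, eff in cfg.differential_species:
        i = species.index(sp)
        mask = np.array([g == grp for g in groups])
        species_abund[i, mask] *= 2.0 ** eff
    species_abund_df = pd.DataFrame(species_abund, index=species, columns=sample_ids)

    # --- gene abundance: species signal x fixed per-gene factor x noise
    gene_factor = np.exp(rng.normal(0.0, cfg.gene_factor_sigma, size=len(gene_ids)))
    sp_index = np.array([species.index(gene_species[g]) for g in gene_ids])
    noise = np.exp(
        rng.normal(0.0, cfg.gene_noise_sigma, size=(len(gene_ids), n_samples))
    )
    gene_abund = species_abund[sp_index] * gene_factor[:, None] * noise

    # --- KO / module assignment: planted modules get reserved KOs carried
    # by differential-species genes; null modules are random subsets of the
    # background KOs that ordinary genes draw from (so they are scored).
    ko_universe = [f"K{i:05d}" for i in range(cfg.n_ko)]
    need = len(cfg.enriched_modules) * cfg.module_size
    if need + cfg.module_size > cfg.n_ko:
        raise ValueError("n_ko too small for the requested modules")
    background_kos = ko_universe[: cfg.n_ko - need]
    module_kos: dict[str, list[str]] = {}
    cursor = cfg.n_ko - need
    for mod, _, _ in cfg.enriched_modules:
        module_kos[mod] = ko_universe[cursor : cursor + cfg.module_size]
        cursor += cfg.module_size
    for i in range(cfg.n_null_modules):
        module_kos[f"M9{i + 1:03d}"] = sorted(
            rng.choice(
                background_kos,
                size=min(cfg.module_size, len(background_kos)),
                replace=False,
            )
        )

    gene_to_terms: dict[str, set[str]] = {}
    carrier_of: dict[str, tuple[str, float]] = {}  # gene -> (target group, shift)
    for mod, grp, shift in cfg.enriched_modules:
        host_species = [sp for sp, d, _ in cfg.differential_species if d == grp]
        host_genes = [g for sp in host_species for g in species_genes[sp]]
        pos = 0
        for ko in module_kos[mod]:
            for _ in range(cfg.carriers_per_ko):
                g = host_genes[pos % len(host_genes)]
                pos += 1
                gene_to_terms.setdefault(g, set()).add(ko)
                carrier_of[g] = (grp, shift)
    for gi, g in enumerate(gene_ids):
        if g in gene_to_terms:
            continue
        if background_kos and rng.random() < cfg.annotation_rate:
            gene_to_terms[g] = {background_kos[rng.integers(len(background_kos))]}

    # per-KO shift: carrier genes get an extra fold-change in the target group
    group_arr = np.array(groups)
    for gi, g in enumerate(gene_ids):
        if g in carrier_of:
            grp, shift = carrier_of[g]
            gene_abund[gi, group_arr == grp] *= 2.0 ** shift

    rel = gene_abund / gene_abund.sum(axis=0, keepdims=True)
    true_abund = AbundanceMatrix(
        pd.DataFrame(rel, index=gene_ids, columns=sample_ids), relative=True
    )

    # --- gene lengths (log-normal, median ~750 bp, ORF floor 100 bp)
    lengths = np.maximum(
        100, np.round(np.exp(rng.normal(np.log(750.0), 0.35, size=len(gene_ids))))
    ).astype(np.int64)
    gene_table = GeneTable(pd.Series(lengths, index=gene_ids, name="length_bp"))

    # --- counts: multinomial thinning of length-weighted abundance
    weights = rel * lengths[:, None]
    weights /= weights.sum(axis=0, keepdims=True)
    counts = np.column_stack(
        [rng.multinomial(cfg.depth, weights[:, j]) for j in range(n_samples)]
    )
    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    )

    # --- best-hit taxonomy, with a contaminated wrong-lineage fraction
    lineages = _species_lineages(species)
    rows = []
    contaminated = rng.random(len(gene_ids)) < cfg.contamination_rate
    for gi, g in enumerate(gene_ids):
        sp = gene_species[g]
        if contaminated[gi] and len(species) > 1:
            others = [s for s in species if s != sp]
            sp = others[rng.integers(len(others))]
        rows.append(
            {
                "gene_id": g,
                "lineage": format_lineage(lineages[sp]),
                "pct_identity": round(float(rng.uniform(96.0, 100.0)), 2),
                "pct_overlap": round(float(rng.uniform(91.0, 100.0)), 2),
            }
        )
    hits = GeneHits(pd.DataFrame(rows))

    # --- nutrients: Gaussian copula on species-profile ranks
    nut = pd.DataFrame(
        rng.normal(50.0, 10.0, size=(n_samples, len(cfg.nutrient_ids))),
        index=sample_ids,
        columns=list(cfg.nutrient_ids),
    )
    from scipy import stats as _stats

    for sp, nutrient, rho in cfg.diet_correlated:
        # latent correlation chosen so the *Spearman* rho hits the target
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        prof = species_abund_df.loc[sp].to_numpy()
        ranks = _stats.rankdata(prof)
        z = _stats.norm.ppf((ranks - 0.375) / (n_samples + 0.25))
        eps = rng.normal(size=n_samples)
        nut[nutrient] = 50.0 + 10.0 * (r * z + np.sqrt(max(0.0, 1 - r * r)) * eps)
    nutrients = NutrientTable(nut)

    labels = CohortLabels(pd.Series(groups, index=sample_ids, name="group"))
    truth = SyntheticTruth(
        species_genes=species_genes,
        species_lineage={sp: format_lineage(lineages[sp]) for sp in species},
        differential_species=list(cfg.differential_species),
        enriched_modules=list(cfg.enriched_modules),
        diet_correlated=list(cfg.diet_correlated),
    )
    annotations = AnnotationMap(
        gene_to_terms={g: set(t) for g, t in gene_to_terms.items()},
        modules={m: set(k) for m, k in module_kos.items()},
    )
    return SyntheticDataset(
        counts=count_matrix,
        genes=gene_table,
        labels=labels,
        hits=hits,
        annotations=annotations,
        nutrients=nutrients,
        truth=truth,
        true_abundance=true_abund,
        species_abundance=species_abund_df,
    )


def truth_recovery_report(
    truth: SyntheticTruth,
    mgs_bins,
    diff_result: pd.DataFrame | None = None,
    reporter_result: pd.DataFrame | None = None,
    diet_result: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Score recovered structure against the planted truth.

    Returns a flat metric dict: adjusted Rand index between the planted
    species partition and the recovered MGS partition (restricted to
    clustered genes), per-species direction accuracy for the planted
    differential species, module-enrichment precision/recall, and the
    fraction of planted diet pairs flagged significant.
    """
    from sklearn.metrics import adjusted_rand_score

    gene_species = {g: sp for sp, genes in truth.species_genes.items() for g in genes}
    clustered_genes, pred = [], []
    for b in mgs_bins:
        for g in b.gene_ids:
            if g not in gene_species:
                raise ValueError(f"clustered gene {g!r} unknown to the truth record")
            clustered_genes.append(g)
            pred.append(b.mgs_id)
    report: dict[str, float] = {
        "n_mgs": float(len(mgs_bins)),
        "n_clustered_genes": float(len(clustered_genes)),
    }
    if clustered_genes:
        true_lab = [gene_species[g] for g in clustered_genes]
        report["ari"] = float(adjusted_rand_score(true_lab, pred))
    else:
        report["ari"] = float("nan")

    if truth.differential_species:
        correct = recovered = 0
        for sp, grp, _ in truth.differential_species:
            sp_genes = set(truth.species_genes[sp])
            best, overlap = None, 0
            for b in mgs_bins:
                ov = len(sp_genes & set(b.gene_ids))
                if ov > overlap:
                    best, overlap = b, ov
            if best is not None:
                recovered += 1
                if best.enriched_in == grp:
                    correct += 1
        n_diff = len(truth.differential_species)
        report["species_recovered_fraction"] = recovered / n_diff
        report["species_direction_accuracy"] = (
            correct / recovered if recovered else 0.0
        )

    if reporter_result is not None and truth.enriched_modules:
        planted = {(m, g) for m, g, _ in truth.enriched_modules}
        called = {
            (m, row["direction"])
            for m, row in reporter_result.iterrows()
            if row["enriched"]
        }
        tp = len(planted & called)
        report["module_precision"] = tp / len(called) if called else 0.0
        report["module_recall"] = tp / len(planted)

    if diet_result is not None and truth.diet_correlated:
        mgs_by_species = {}
        for sp, genes in truth.species_genes.items():
            sp_genes = set(genes)
            for b in mgs_bins:
                if len(sp_genes & set(b.gene_ids)) > len(sp_genes) / 2:
                    mgs_by_species[sp] = b.mgs_id
        flagged = total = 0
        for sp, nutrient, _rho in truth.diet_correlated:
            mid = mgs_by_species.get(sp)
            if mid is None:
                total += 1
                continue
            cell = diet_result[
                (diet_result["mgs_id"] == mid)
                & (diet_result["nutrient_id"] == nutrient)
            ]
            total += 1
            if len(cell) and cell.iloc[0]["flag"] in ("+", "*"):
                flagged += 1
        report["diet_flagged_fraction"] = flagged / total if total else 0.0
    return report


def write_run_dir(ds: SyntheticDataset, out_dir, cfg: SimulationConfig | None = None) -> None:
    """Emit the seven tables (plus truth and a manifest) as TSV/JSON."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_count_matrix(ds.counts, out / "counts.tsv")
    _io.write_gene_table(ds.genes, out / "genes.tsv")
    _io.write_labels(ds.labels, out / "labels.tsv")
    _io.write_gene_hits(ds.hits, out / "hits.tsv")
    _io.write_annotation_map(ds.annotations, out / "gene_ko.tsv", out / "modules.tsv")
    _io.write_nutrient_table(ds.nutrients, out / "nutrients.tsv")
    truth = dataclasses.asdict(ds.truth)
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    if cfg is not None:
        manifest = dataclasses.asdict(cfg)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=list)
        )
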