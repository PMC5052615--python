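"""Domain types and tabular readers/writers shared by all pipeline stages.

All tables are UTF-8 TSV with a header row; matrices are oriented
rows = features (genes, KOs, species, MGS), columns = samples.  Joins
across tables always align by identifier, never by position.  ``NA``
denotes a missing cell in nutrient tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "RANK_PREFIXES",
    "FormatError",
    "CountMatrix",
    "GeneTable",
    "AbundanceMatrix",
    "CohortLabels",
    "GeneHits",
    "AnnotationMap",
    "NutrientTable",
    "MGSNetwork",
    "parse_lineage",
    "format_lineage",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_table",
    "write_gene_table",
    "read_abundance_matrix",
    "write_abundance_matrix",
    "read_labels",
    "write_labels",
    "read_gene_hits",
    "write_gene_hits",
    "read_annotation_map",
    "write_annotation_map",
    "read_nutrient_table",
    "write_nutrient_table",
    "write_network",
    "read_network_graphml",
]

#: Taxonomic ranks ordered from shallowest to deepest.
RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

#: Single-letter prefixes used in semicolon-separated lineage strings
#: (``k__Bacteria;p__Firmicutes;...;t__SomeStrain``).
RANK_PREFIXES = dict(
    zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__"))
)


class FormatError(ValueError):
    """Raised when an input table violates the documented format."""


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dup = s[s.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {dup}")


@dataclass
class CountMatrix:
    """Mapped read-pair counts, genes x samples.

    Only read pairs where both mates map to the same catalogue gene are
    counted, so every entry is a whole number of pairs.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("count matrix has non-numeric entries")
        if np.any(vals < 0):
            r, c = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            raise FormatError("count matrix has non-integer entries")
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class GeneTable:
    """Per-gene length in bp; catalogue ORFs are at least 100 bp."""

    lengths: pd.Series  # index gene_id -> length_bp

    def __post_init__(self) -> None:
        _check_unique(self.lengths.index, "gene")
        self.lengths = self.lengths.astype(np.int64)
        if (self.lengths < 100).any():
            bad = self.lengths.index[self.lengths < 100][0]
            raise FormatError(f"gene {bad!r} shorter than the 100 bp threshold")


@dataclass
class AbundanceMatrix:
    """Feature x sample real-valued abundances.

    When ``relative`` is set every sample column must sum to 1 (within
    1e-9) and all-zero columns are forbidden.
    """

    values: pd.DataFrame
    relative: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise FormatError("negative abundance value")
        if self.relative:
            sums = vals.sum(axis=0)
            if np.any(sums == 0):
                bad = self.values.columns[np.argwhere(sums == 0)[0][0]]
                raise FormatError(f"all-zero sample column {bad!r}")
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = self.values.columns[np.argmax(np.abs(sums - 1.0))]
                raise FormatError(
                    f"relative abundance column {bad!r} does not sum to 1"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CohortLabels:
    """sample_id -> cohort label; two-group stages require exactly two groups."""

    labels: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "sample")
        counts = self.labels.value_counts()
        if (counts < 2).any():
            small = counts.index[counts < 2].tolist()
            raise FormatError(f"group(s) with fewer than 2 samples: {small}")

    @property
    def groups(self) -> list[str]:
        # first-appearance order, so the focal group is stable across runs
        return list(dict.fromkeys(self.labels))

    def two_groups(self) -> tuple[str, str]:
        g = self.groups
        if len(g) != 2:
            raise FormatError(
                f"expected exactly two groups, found {len(g)}: {g}; "
                "run two-group stages pairwise"
            )
        return g[0], g[1]

    def samples_of(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])


@dataclass
class GeneHits:
    """Per-gene best-hit taxonomy: lineage plus percent identity/overlap.

    ``table`` columns: ``gene_id``, ``lineage`` (rank-prefixed,
    semicolon-separated), ``pct_identity``, ``pct_overlap``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "lineage", "pct_identity", "pct_overlap"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"gene hit table missing column(s): {sorted(missing)}")
        _check_unique(self.table["gene_id"], "gene")
        for col in ("pct_identity", "pct_overlap"):
            v = self.table[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 100)):
                raise FormatError(f"{col} outside [0, 100]")
        self.table = self.table.set_index("gene_id", drop=False)

    def lineage_of(self, gene_id: str) -> dict[str, str]:
        return parse_lineage(self.table.at[gene_id, "lineage"])


@dataclass
class AnnotationMap:
    """gene_id -> set of KO/OG terms, and module_id -> set of member KOs."""

    gene_to_terms: dict[str, set[str]] = field(default_factory=dict)
    modules: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mod, kos in self.modules.items():
            if not kos:
                raise FormatError(f"module {mod!r} has no member KOs")


@dataclass
class NutrientTable:
    """Sample x nutrient values from food-frequency questionnaires.

    Missing cells are NaN and are excluded pairwise from correlations.
    """

    values: pd.DataFrame  # rows samples, columns nutrients

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "nutrient")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def nutrient_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MGSNetwork:
    """Undirected MGS co-occurrence network.

    Nodes carry mean relative abundance and an order-level taxon used as
    color key; edges carry the Spearman rho that put them above the
    threshold (strictly greater).
    """

    graph: nx.Graph
    rho_min: float = 0.6

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise FormatError(f"self-edge on node {u!r}")
            if not d.get("rho", 0.0) > self.rho_min:
                raise FormatError(
                    f"edge ({u!r}, {v!r}) rho {d.get('rho')} not > {self.rho_min}"
                )


# ---------------------------------------------------------------------------
# lineage helpers


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse ``k__X;p__Y;...`` into an ordered rank -> name mapping.

    Deeper ranks may be absent; empty fields (``s__``) are dropped.
    """
    out: dict[str, str] = {}
    prefix_to_rank = {v: k for k, v in RANK_PREFIXES.items()}
    for part in str(lineage).split(";"):
        part = part.strip()
        if len(part) >= 3 and part[:3] in prefix_to_rank and part[3:]:
            out[prefix_to_rank[part[:3]]] = part[3:]
    return {r: out[r] for r in RANKS if r in out}


def format_lineage(names: dict[str, str]) -> str:
    return ";".join(RANK_PREFIXES[r] + names[r] for r in RANKS if r in names)


# ---------------------------------------------------------------------------
# readers / writers


def _read_matrix(path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, index_name)
    _check_unique(df.columns, "sample")
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise FormatError(
                f"non-numeric cell at row {df.index[i]!r}, column {col!r}"
            )
        df[col] = coerced
    return df


def read_count_matrix(path) -> CountMatrix:
    """Read a gene x sample mapped-pair count TSV (first column gene ids)."""
    return CountMatrix(_read_matrix(path, "gene"))


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_gene_table(path) -> GeneTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "length_bp"} <= set(df.columns):
        raise FormatError("gene table needs columns gene_id, length_bp")
    return GeneTable(df.set_index("gene_id")["length_bp"])


def write_gene_table(gt: GeneTable, path) -> None:
    gt.lengths.rename("length_bp").rename_axis("gene_id").to_csv(path, sep="\t")


def read_abundance_matrix(path, relative: bool = False) -> AbundanceMatrix:
    return AbundanceMatrix(_read_matrix(path, "feature"), relative=relative)


def write_abundance_matrix(am: AbundanceMatrix, path) -> None:
    am.values.rename_axis("feature_id").to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_labels(path) -> CohortLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise FormatError("label table needs columns sample_id, group")
    return CohortLabels(df.set_index("sample_id")["group"])


def write_labels(labels: CohortLabels, path) -> None:
    labels.labels.rename("group").rename_axis("sample_id").to_csv(path, sep="\t")


def read_gene_hits(path) -> GeneHits:
    return GeneHits(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))


def write_gene_hits(hits: GeneHits, path) -> None:
    hits.table.to_csv(path, sep="\t", index=False, float_format="%.4g")


def read_annotation_map(gene_term_path, module_path=None) -> AnnotationMap:
    """Read gene->term pairs and optional module->KO pairs (one pair per row)."""
    pairs = pd.read_csv(gene_term_path, sep="\t", dtype=str)
    if not {"gene_id", "term"} <= set(pairs.columns):
        raise FormatError("annotation table needs columns gene_id, term")
    gene_to_terms: dict[str, set[str]] = {}
    for g, t in zip(pairs["gene_id"], pairs["term"]):
        gene_to_terms.setdefault(g, set()).add(t)
    modules: dict[str, set[str]] = {}
    if module_path is not None:
        mod = pd.read_csv(module_path, sep="\t", dtype=str)
        if not {"module_id", "term"} <= set(mod.columns):
            raise FormatError("module table needs columns module_id, term")
        for m, t in zip(mod["module_id"], mod["term"]):
            modules.setdefault(m, set()).add(t)
    return AnnotationMap(gene_to_terms, modules)


def write_annotation_map(ann: AnnotationMap, gene_term_path, module_path=None) -> None:
    rows = [
        (g, t) for g in sorted(ann.gene_to_terms) for t in sorted(ann.gene_to_terms[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(
        gene_term_path, sep="\t", index=False
    )
    if module_path is not None:
        rows = [(m, t) for m in sorted(ann.modules) for t in sorted(ann.modules[m])]
        pd.DataFrame(rows, columns=["module_id", "term"]).to_csv(
            module_path, sep="\t", index=False
        )


def read_nutrient_table(path) -> NutrientTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return NutrientTable(df.astype(float))


def write_nutrient_table(nt: NutrientTable, path) -> None:
    nt.values.rename_axis("sample_id").to_csv(
        path, sep="\t", na_rep="NA", float_format="%.10g"
    )


def write_network(net: MGSNetwork, path, format: str = "graphml") -> None:
    """Export the MGS network as GraphML or a TSV edge list (rho, 6 dp)."""
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\trho\n")
            for u, v, d in sorted(net.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['rho']:.6f}\n")
    else:
        raise ValueError(f"unknown network format {format!r}; use graphml or edgelist")


def read_network_graphml(path, rho_min: float = 0.0) -> MGSNetwork:
    return MGSNetwork(nx.read_graphml(path), rho_min=rho_min)
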