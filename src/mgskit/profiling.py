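"""Gene abundance profiling and aggregation to functional/taxonomic features.

Gene relative abundance follows the length-normalisation used by the
MetaHIT-style catalogue pipelines: for gene g with mapped-pair count x_g
and length L_g, a_g = (x_g / L_g) / sum_j (x_j / L_j), per sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import (
    RANKS,
    AbundanceMatrix,
    AnnotationMap,
    CountMatrix,
    FormatError,
    GeneHits,
    GeneTable,
    parse_lineage,
)

__all__ = [
    "gene_relative_abundance",
    "aggregate_by_annotation",
    "aggregate_by_taxon",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "unclassified"


def gene_relative_abundance(counts: CountMatrix, genes: GeneTable) -> AbundanceMatrix:
    """Length-normalised per-sample relative gene abundance.

    Raises if a gene lacks a length or a sample has no mapped pairs.
    """
    missing = set(counts.gene_ids) - set(genes.lengths.index)
    if missing:
        raise FormatError(f"gene(s) missing from length table: {sorted(missing)[:5]}")
    lengths = genes.lengths.loc[counts.counts.index].to_numpy(dtype=float)
    x = counts.counts.to_numpy(dtype=float)
    col_tot = x.sum(axis=0)
    if np.any(col_tot == 0):
        bad = counts.counts.columns[np.argwhere(col_tot == 0)[0][0]]
        raise FormatError(f"sample {bad!r} has no mapped read pairs")
    rate = x / lengths[:, None]
    abund = rate / rate.sum(axis=0, keepdims=True)
    return AbundanceMatrix(
        pd.DataFrame(abund, index=counts.counts.index, columns=counts.counts.columns),
        relative=True,
    )


def aggregate_by_annotation(
    abund: AbundanceMatrix,
    ann: AnnotationMap,
    split_multi: bool = False,
) -> AbundanceMatrix:
    """Accumulate gene abundances into KO/OG feature abundances.

    A gene annotated to several terms contributes its full abundance to
    each of them by default (documented double-counting); with
    ``split_multi`` its abundance is divided equally among its terms.
    Unannotated genes contribute to no feature, so column sums may drop
    below 1.
    """
    if not ann.gene_to_terms:
        raise FormatError("empty annotation map")
    gene_index = {g: i for i, g in enumerate(abund.values.index)}
    vals = abund.values.to_numpy(dtype=float)
    terms = sorted({t for ts in ann.gene_to_terms.values() for t in ts})
    term_index = {t: i for i, t in enumerate(terms)}
    out = np.zeros((len(terms), vals.shape[1]))
    for g, ts in ann.gene_to_terms.items():
        gi = gene_index.get(g)
        if gi is None:
            continue
        w = 1.0 / len(ts) if split_multi else 1.0
        for t in ts:
            out[term_index[t]] += w * vals[gi]
    return AbundanceMatrix(
        pd.DataFrame(out, index=terms, columns=abund.values.columns)
    )


def aggregate_by_taxon(
    abund: AbundanceMatrix,
    hits: GeneHits,
    rank: str,
    identity_min: float = 95.0,
    overlap_min: float = 90.0,
    keep_unclassified: bool = True,
) -> AbundanceMatrix:
    """Sum gene abundances by the named rank of each gene's best hit.

    Only hits with identity strictly above ``identity_min`` and overlap
    strictly above ``overlap_min`` qualify; genes without a qualifying
    hit (or absent from the hit table, or unresolved at ``rank``) are
    pooled under ``unclassified`` so columns still sum to 1.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {list(RANKS)}")
    taxa = {}
    t = hits.table
    qual = (t["pct_identity"] > identity_min) & (t["pct_overlap"] > overlap_min)
    for gene_id, lineage in zip(t.loc[qual, "gene_id"], t.loc[qual, "lineage"]):
        name = parse_lineage(lineage).get(rank)
        if name is not None:
            taxa[gene_id] = name
    labels = [taxa.get(g, UNCLASSIFIED) for g in abund.values.index]
    grouped = abund.values.groupby(pd.Index(labels, name=rank), sort=True).sum()
    if not keep_unclassified and UNCLASSIFIED in grouped.index:
        grouped = grouped.drop(index=UNCLASSIFIED)
    return AbundanceMatrix(grouped, relative=abund.relative and keep_unclassified)
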