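"""Metagenomic species (MGS): co-abundance clustering of differential genes.

Genes whose abundance profiles are Spearman-correlated above 0.8 across
all samples (both cohorts pooled) are clustered by single linkage —
implemented as connected components of the thresholded correlation
graph, which is the same partition.  Clusters with more than 25 genes
are then iteratively fused while their representative profiles (per-
sample median) stay correlated above 0.8; smaller clusters never become
MGS.  Each MGS gets up to 25 "tracer" genes (the members tracking the
cluster median best), an abundance profile (per-sample median of the
tracers), a consensus taxonomic assignment, and membership in a
co-occurrence network linking MGS with Spearman rho > 0.6.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import RANKS, AbundanceMatrix, GeneHits, MGSNetwork, parse_lineage

__all__ = [
    "MGSBin",
    "spearman_matrix",
    "single_linkage_clusters",
    "fuse_clusters",
    "select_tracers",
    "mgs_profile",
    "assign_taxonomy",
    "build_network",
    "cluster_mgs",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: correlations within EPS of a threshold count as equal to it, so a pair
#: at exactly the threshold is never linked despite float representation
EPS = 1e-9


@dataclass
class MGSBin:
    """One metagenomic species: a co-abundant gene cluster."""

    mgs_id: str
    gene_ids: list[str]
    tracer_gene_ids: list[str] = field(default_factory=list)
    profile: pd.Series | None = None  # per-sample abundance
    taxon: str = UNASSIGNED
    taxon_rank: str | None = None
    enriched_in: str | None = None

    def __post_init__(self) -> None:
        if self.tracer_gene_ids and not set(self.tracer_gene_ids) <= set(self.gene_ids):
            raise ValueError(f"{self.mgs_id}: tracer genes not a subset of members")

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def spearman_matrix(abund: AbundanceMatrix, feature_subset=None) -> pd.DataFrame:
    """All-pairs Spearman rho across samples (average ranks for ties).

    Constant features have undefined rank correlation; their rho is
    recorded as 0 with a warning, and the diagonal is forced to 1.
    """
    mat = abund.values if feature_subset is None else abund.values.loc[list(feature_subset)]
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    if mat.shape[0] == 0:
        raise ValueError("empty feature subset")
    x = mat.to_numpy(dtype=float)
    constant = np.ptp(x, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s): rho recorded as 0",
            stacklevel=2,
        )
    ranks = stats.rankdata(x, axis=1)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.atleast_2d(rho)
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=mat.index, columns=mat.index)


def single_linkage_clusters(rho: pd.DataFrame, threshold: float = 0.8) -> list[list[str]]:
    """Partition features by single-linkage at similarity ``threshold``.

    Single-linkage clustering cut at rho > threshold is exactly the set
    of connected components of the graph with an edge wherever
    rho > threshold (strict).  Singletons are returned too.  Output is
    deterministic: clusters ordered by first member, members sorted.
    """
    adj = csr_matrix((rho.to_numpy() > threshold + EPS).astype(np.int8))
    n_comp, comp = connected_components(adj, directed=False)
    ids = np.asarray(rho.index)
    clusters: dict[int, list[str]] = {}
    for label, gene in zip(comp, ids):
        clusters.setdefault(int(label), []).append(str(gene))
    out = [sorted(members) for members in clusters.values()]
    out.sort(key=lambda c: c[0])
    return out


def _representative(abund: pd.DataFrame, genes: list[str]) -> np.ndarray:
    """Cluster representative profile: per-sample median over member genes."""
    return np.median(abund.loc[genes].to_numpy(dtype=float), axis=0)


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def fuse_clusters(
    partition: list[list[str]],
    abund: AbundanceMatrix,
    min_size: int = 25,
    threshold: float = 0.8,
) -> tuple[list[MGSBin], list[list[str]]]:
    """Fuse large co-abundant clusters and return the MGS list.

    Clusters with more than ``min_size`` genes are eligible.  The pair
    of eligible clusters whose representative profiles (per-sample
    median) have the highest Spearman rho is fused, the representative
    recomputed, and the step repeated while that rho exceeds
    ``threshold``; ties break towards the lexicographically smaller
    pair.  Clusters of <= ``min_size`` genes are never reported as MGS;
    they are returned as a side list.
    """
    mat = abund.values
    eligible = sorted(
        (sorted(c) for c in partition if len(c) > min_size), key=lambda c: c[0]
    )
    small = [sorted(c) for c in partition if len(c) <= min_size]
    reps = {i: _representative(mat, c) for i, c in enumerate(eligible)}
    members = {i: list(c) for i, c in enumerate(eligible)}

    while len(members) > 1:
        best = None  # (rho, key_i, key_j)
        keys = sorted(members, key=lambda k: members[k][0])
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                i, j = keys[a], keys[b]
                r = _spearman_pair(reps[i], reps[j])
                if best is None or r > best[0] + 1e-15:
                    best = (r, i, j)
        if best is None or best[0] <= threshold + EPS:
            break
        _, i, j = best
        members[i] = sorted(members[i] + members[j])
        del members[j], reps[j]
        reps[i] = _representative(mat, members[i])
        logger.info("fused clusters into one of %d genes", len(members[i]))

    bins = [
        MGSBin(mgs_id=f"MGS{k + 1:03d}", gene_ids=genes)
        for k, genes in enumerate(
            sorted(members.values(), key=lambda c: (-len(c), c[0]))
        )
    ]
    return bins, small


def select_tracers(mgs: MGSBin, abund: AbundanceMatrix, k: int = 25) -> list[str]:
    """Pick the k member genes tracking the cluster median profile best.

    Ranked by Spearman rho to the per-sample median of all members; ties
    break towards higher mean abundance, then lexicographic gene id.
    """
    if not mgs.gene_ids:
        raise ValueError("empty MGS")
    genes = sorted(mgs.gene_ids)
    if len(genes) <= k:
        return genes
    mat = abund.values.loc[genes].to_numpy(dtype=float)
    rep = np.median(mat, axis=0)
    scored = [
        (-_spearman_pair(mat[i], rep), -mat[i].mean(), g)
        for i, g in enumerate(genes)
    ]
    scored.sort()
    return [g for _, _, g in scored[:k]]


def mgs_profile(mgs: MGSBin, abund: AbundanceMatrix) -> pd.Series:
    """MGS abundance: per-sample median over the tracer genes."""
    genes = mgs.tracer_gene_ids or sorted(mgs.gene_ids)
    prof = abund.values.loc[genes].median(axis=0)
    prof.name = mgs.mgs_id
    return prof


def assign_taxonomy(
    mgs: MGSBin,
    hits: GeneHits,
    identity_min: float = 95.0,
    overlap_min: float = 90.0,
    consensus: float = 0.90,
    lenient: bool = False,
) -> tuple[str, str | None]:
    """Consensus taxonomy: deepest rank where one name covers > 90% of genes.

    Only best hits with identity strictly above ``identity_min`` and
    overlap strictly above ``overlap_min`` qualify.  Ranks are walked
    from strain up to superkingdom and the deepest rank at which a
    single taxon name accounts for more than ``consensus`` of the MGS's
    genes wins.  The denominator is all member genes — genes with no
    qualifying hit count against the consensus — unless ``lenient``,
    which restricts it to genes with a qualifying hit.
    """
    table = hits.table
    lineages: list[dict[str, str]] = []
    for g in mgs.gene_ids:
        if g in table.index:
            row = table.loc[g]
            if row["pct_identity"] > identity_min and row["pct_overlap"] > overlap_min:
                lineages.append(parse_lineage(row["lineage"]))
    denom = len(lineages) if lenient else len(mgs.gene_ids)
    if denom == 0:
        return UNASSIGNED, None
    for rank in reversed(RANKS):  # strain first, superkingdom last
        names = [lin[rank] for lin in lineages if rank in lin]
        if not names:
            continue
        top, count = pd.Series(names).value_counts().reset_index().iloc[0]
        if count / denom > consensus:
            return str(top), rank
    return UNASSIGNED, None


def build_network(
    profiles: AbundanceMatrix,
    rho_min: float = 0.6,
    taxa: dict[str, str] | None = None,
) -> MGSNetwork:
    """MGS co-occurrence network: edges where Spearman rho strictly > rho_min.

    Node attributes: mean relative abundance (drives node size in the
    usual rendering) and an order-level taxon name used as color key.
    """
    if profiles.values.shape[0] < 2:
        raise ValueError("need at least 2 MGS to build a network")
    rho = spearman_matrix(profiles)
    g = nx.Graph()
    means = profiles.values.mean(axis=1)
    for mgs_id in profiles.feature_ids:
        g.add_node(
            mgs_id,
            mean_abundance=float(means[mgs_id]),
            order=(taxa or {}).get(mgs_id, UNASSIGNED),
        )
    ids = profiles.feature_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = float(rho.iloc[i, j])
            if r > rho_min + EPS:
                g.add_edge(ids[i], ids[j], rho=r)
    return MGSNetwork(g, rho_min=rho_min)


def cluster_mgs(
    abund: AbundanceMatrix,
    gene_subset,
    rho_threshold: float = 0.8,
    min_size: int = 25,
    n_tracers: int = 25,
) -> tuple[list[MGSBin], list[list[str]]]:
    """Full MGS pass: correlate, cluster, fuse, pick tracers, profile."""
    rho = spearman_matrix(abund, feature_subset=gene_subset)
    partition = single_linkage_clusters(rho, threshold=rho_threshold)
    bins, small = fuse_clusters(partition, abund, min_size=min_size, threshold=rho_threshold)
    for b in bins:
        b.tracer_gene_ids = select_tracers(b, abund, k=n_tracers)
        b.profile = mgs_profile(b, abund)
    return bins, small
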