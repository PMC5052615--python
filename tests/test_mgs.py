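import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from mgskit.io import GeneHits
from mgskit.mgs import (
    UNASSIGNED,
    MGSBin,
    assign_taxonomy,
    build_network,
    fuse_clusters,
    mgs_profile,
    select_tracers,
    single_linkage_clusters,
    spearman_matrix,
)

from .conftest import make_abundance


def _latent_cluster_abundance(rng, sizes, n_samples=60, noise=0.25):
    """Genes in block i follow latent trajectory i times log-normal noise."""
    rows, names = [], []
    for bi, size in enumerate(sizes):
        latent = np.exp(rng.normal(0, 1, n_samples))
        for g in range(size):
            rows.append(latent * np.exp(rng.normal(0, noise, n_samples)))
            names.append(f"b{bi}.g{g:03d}")
    return make_abundance(np.array(rows), feature_ids=names)


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self):
        ab = make_abundance(np.random.default_rng(0).random((3, 10)))
        rho = spearman_matrix(ab)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_monotone_transform_gives_rho_one(self):
        x = np.linspace(0.1, 2.0, 12)
        ab = make_abundance(np.vstack([x, np.exp(x)]))
        assert spearman_matrix(ab).iloc[0, 1] == pytest.approx(1.0)

    def test_textbook_rank_formula_case(self):
        # x=(1,2,3,4), y=(2,1,4,3): 1 - 6*4/(4*15) = 0.6
        ab = make_abundance([[1, 2, 3, 4], [2, 1, 4, 3]])
        assert spearman_matrix(ab).iloc[0, 1] == pytest.approx(0.6)

    def test_constant_feature_recorded_as_zero_with_warning(self):
        ab = make_abundance([[1, 1, 1, 1], [1, 2, 3, 4.0]])
        with pytest.warns(UserWarning, match="constant"):
            rho = spearman_matrix(ab)
        assert rho.iloc[0, 1] == 0.0
        assert rho.iloc[0, 0] == 1.0

    def test_agrees_with_scipy_spearmanr(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        x = rng.random((6, 15))
        rho = spearman_matrix(make_abundance(x))
        expected = stats.spearmanr(x, axis=1).statistic
        np.testing.assert_allclose(rho.to_numpy(), expected, atol=1e-12)


class TestSingleLinkage:
    def _rho(self, pairs, n, ids=None):
        ids = ids or [chr(ord("a") + i) for i in range(n)]
        m = np.eye(n)
        for i, j, r in pairs:
            m[i, j] = m[j, i] = r
        return pd.DataFrame(m, index=ids, columns=ids)

    def test_chain_components_by_hand(self):
        # a-b (0.9), b-c (0.85), c-d (0.5) -> {a,b,c}, {d}
        rho = self._rho([(0, 1, 0.9), (1, 2, 0.85), (2, 3, 0.5)], 4)
        assert single_linkage_clusters(rho, 0.8) == [["a", "b", "c"], ["d"]]

    def test_no_pair_above_threshold_gives_singletons(self):
        rho = self._rho([(0, 1, 0.8)], 3)  # exactly at threshold: no edge
        assert single_linkage_clusters(rho, 0.8) == [["a"], ["b"], ["c"]]

    def test_matches_dendrogram_cut_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            ab = _latent_cluster_abundance(rng, [10, 12, 8, 10], noise=0.6)
            rho = spearman_matrix(ab)
            ours = {frozenset(c) for c in single_linkage_clusters(rho, 0.8)}
            d = 1.0 - rho.to_numpy()
            np.fill_diagonal(d, 0.0)
            z = linkage(squareform(d, checks=False), method="single")
            flat = fcluster(z, t=0.2 - 1e-9, criterion="distance")
            theirs = {
                frozenset(rho.index[flat == k]) for k in np.unique(flat)
            }
            assert ours == theirs

    def test_invariant_to_gene_ordering(self):
        rng = np.random.default_rng(12)
        ab = _latent_cluster_abundance(rng, [8, 8])
        rho = spearman_matrix(ab)
        perm = rng.permutation(len(rho))
        shuffled = rho.iloc[perm, perm]
        assert {frozenset(c) for c in single_linkage_clusters(rho)} == {
            frozenset(c) for c in single_linkage_clusters(shuffled)
        }


class TestFuseClusters:
    def test_artificially_split_species_is_refused(self):
        rng = np.random.default_rng(42)
        ab = _latent_cluster_abundance(rng, [60])
        genes = ab.feature_ids
        partition = [genes[:30], genes[30:]]  # one species, split in two
        bins, small = fuse_clusters(partition, ab, min_size=25, threshold=0.8)
        assert len(bins) == 1
        assert bins[0].size == 60
        assert small == []

    def test_small_cluster_never_becomes_mgs(self):
        rng = np.random.default_rng(43)
        ab = _latent_cluster_abundance(rng, [30, 10])
        genes = ab.feature_ids
        partition = [genes[:30], genes[30:]]
        bins, small = fuse_clusters(partition, ab, min_size=25)
        assert [b.size for b in bins] == [30]
        assert len(small) == 1 and len(small[0]) == 10

    def test_boundary_exactly_min_size_is_excluded(self):
        rng = np.random.default_rng(44)
        ab = _latent_cluster_abundance(rng, [25])
        bins, small = fuse_clusters([ab.feature_ids], ab, min_size=25)
        assert bins == [] and len(small[0]) == 25

    def test_independent_species_stay_separate(self):
        rng = np.random.default_rng(45)
        for _ in range(10):
            ab = _latent_cluster_abundance(rng, [30, 30], noise=0.3)
            genes = ab.feature_ids
            bins, _ = fuse_clusters([genes[:30], genes[30:]], ab)
            assert len(bins) == 2

    def test_never_fuses_pair_below_threshold(self):
        rng = np.random.default_rng(46)
        ab = _latent_cluster_abundance(rng, [30, 30, 30], noise=0.3)
        genes = ab.feature_ids
        partition = [genes[:30], genes[30:60], genes[60:]]
        bins, _ = fuse_clusters(partition, ab, threshold=0.99)
        assert len(bins) == 3


class TestTracersAndProfile:
    def test_small_mgs_keeps_all_members_as_tracers(self):
        rng = np.random.default_rng(50)
        ab = _latent_cluster_abundance(rng, [10])
        b = MGSBin("MGS001", ab.feature_ids)
        assert select_tracers(b, ab, k=25) == sorted(ab.feature_ids)

    def test_large_mgs_gets_exactly_k_deterministic_tracers(self):
        rng = np.random.default_rng(51)
        ab = _latent_cluster_abundance(rng, [30])
        b = MGSBin("MGS001", ab.feature_ids)
        t1 = select_tracers(b, ab, k=25)
        t2 = select_tracers(b, ab, k=25)
        assert len(t1) == 25 and t1 == t2

    def test_tracer_set_invariant_to_input_order(self):
        rng = np.random.default_rng(52)
        ab = _latent_cluster_abundance(rng, [30])
        genes = ab.feature_ids
        b1 = MGSBin("m", list(genes))
        b2 = MGSBin("m", list(reversed(genes)))
        assert select_tracers(b1, ab) == select_tracers(b2, ab)

    def test_profile_is_tracer_median(self):
        ab = make_abundance([[0.1, 0.5], [0.2, 0.4], [0.6, 0.3]])
        b = MGSBin("m", ["f0", "f1", "f2"], tracer_gene_ids=["f0", "f1", "f2"])
        prof = mgs_profile(b, ab)
        np.testing.assert_allclose(prof.to_numpy(), [0.2, 0.4])

    def test_single_gene_mgs_profile_is_that_gene(self):
        ab = make_abundance([[0.1, 0.9]])
        prof = mgs_profile(MGSBin("m", ["f0"], tracer_gene_ids=["f0"]), ab)
        np.testing.assert_allclose(prof.to_numpy(), [0.1, 0.9])

    def test_profile_homogeneous_in_scaling(self):
        rng = np.random.default_rng(53)
        x = rng.random((5, 7))
        b = MGSBin("m", [f"f{i}" for i in range(5)])
        p1 = mgs_profile(b, make_abundance(x))
        p2 = mgs_profile(b, make_abundance(3.5 * x))
        np.testing.assert_allclose(p2.to_numpy(), 3.5 * p1.to_numpy())


def _hit_table(rows):
    return GeneHits(
        pd.DataFrame(rows, columns=["gene_id", "lineage", "pct_identity", "pct_overlap"])
    )


class TestAssignTaxonomy:
    def _bin(self, n=100):
        return MGSBin("MGS001", [f"g{i}" for i in range(n)])

    def test_species_level_consensus(self):
        # 95/100 genes with qualifying best hit to species X, strains disagree
        rows = [
            (f"g{i}", f"k__B;g__G;s__X;t__X-{i % 3}", 98.0, 95.0) for i in range(95)
        ]
        taxon, rank = assign_taxonomy(self._bin(), _hit_table(rows))
        assert (taxon, rank) == ("X", "species")

    def test_genus_rescues_species_split(self):
        # 85 species X + 10 species Y, all genus G: species 0.85 <= 0.9, genus 0.95
        rows = [(f"g{i}", "k__B;g__G;s__X", 99.0, 95.0) for i in range(85)]
        rows += [(f"g{i}", "k__B;g__G;s__Y", 99.0, 95.0) for i in range(85, 95)]
        taxon, rank = assign_taxonomy(self._bin(), _hit_table(rows))
        assert (taxon, rank) == ("G", "genus")

    def test_low_identity_hits_leave_mgs_unassigned(self):
        rows = [(f"g{i}", "k__B;s__X", 94.0, 95.0) for i in range(100)]
        assert assign_taxonomy(self._bin(), _hit_table(rows)) == (UNASSIGNED, None)

    def test_exact_90_consensus_is_not_enough(self):
        rows = [(f"g{i}", "k__B;s__X", 99.0, 95.0) for i in range(90)]
        assert assign_taxonomy(self._bin(), _hit_table(rows)) == (UNASSIGNED, None)

    def test_lenient_mode_uses_qualifying_genes_as_denominator(self):
        rows = [(f"g{i}", "k__B;s__X", 99.0, 95.0) for i in range(50)]
        taxon, rank = assign_taxonomy(self._bin(), _hit_table(rows), lenient=True)
        assert (taxon, rank) == ("X", "species")

    def test_gene_absent_from_hit_table_counts_against_consensus(self):
        rows = [(f"g{i}", "k__B;s__X", 99.0, 95.0) for i in range(91)]
        taxon, rank = assign_taxonomy(self._bin(), _hit_table(rows))
        assert (taxon, rank) == ("X", "species")  # 91/100 > 0.90


class TestBuildNetwork:
    def test_correlated_pair_gets_one_edge(self):
        rng = np.random.default_rng(60)
        base = rng.normal(0, 1, 30)
        x = np.exp(np.vstack([base, base + rng.normal(0, 0.7, 30)]))
        net = build_network(make_abundance(x, feature_ids=["m1", "m2"]), rho_min=0.6)
        if net.graph.number_of_edges():
            assert net.graph.edges["m1", "m2"]["rho"] > 0.6

    def test_rho_exactly_at_threshold_is_no_edge(self):
        # profiles engineered to rho = 0.6 exactly (rank formula case)
        x = np.array([[1, 2, 3, 4.0], [2, 1, 4, 3.0], [4, 3, 2, 1.0]])
        net = build_network(make_abundance(x, feature_ids=["m1", "m2", "m3"]))
        assert ("m1", "m2") not in net.graph.edges

    def test_edge_set_matches_brute_force_scan(self):
        from scipy import stats

        rng = np.random.default_rng(61)
        x = np.exp(rng.normal(0, 1, size=(15, 40)))
        x[1] = x[0] * np.exp(rng.normal(0, 0.3, 40))  # force some structure
        x[7] = x[6] * np.exp(rng.normal(0, 0.3, 40))
        ids = [f"m{i:02d}" for i in range(15)]
        net = build_network(make_abundance(x, feature_ids=ids), rho_min=0.6)
        expected = set()
        for i in range(15):
            for j in range(i + 1, 15):
                r = stats.spearmanr(x[i], x[j]).statistic
                if r > 0.6 + 1e-9:  # strict threshold, exact ties excluded
                    expected.add((ids[i], ids[j]))
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == expected

    def test_node_attributes_present(self):
        rng = np.random.default_rng(62)
        x = rng.random((3, 12))
        net = build_network(
            make_abundance(x, feature_ids=["m1", "m2", "m3"]),
            taxa={"m1": "Clostridiales"},
        )
        assert net.graph.nodes["m1"]["order"] == "Clostridiales"
        assert net.graph.nodes["m2"]["order"] == UNASSIGNED
        assert net.graph.nodes["m1"]["mean_abundance"] == pytest.approx(x[0].mean())
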