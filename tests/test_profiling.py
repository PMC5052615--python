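import numpy as np
import pandas as pd
import pytest

from mgskit.io import (
    AnnotationMap,
    CountMatrix,
    FormatError,
    GeneHits,
    GeneTable,
)
from mgskit.profiling import (
    UNCLASSIFIED,
    aggregate_by_annotation,
    aggregate_by_taxon,
    gene_relative_abundance,
)

from .conftest import make_abundance


def _counts(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _genes(lengths, genes=None):
    genes = genes or [f"g{i}" for i in range(len(lengths))]
    return GeneTable(pd.Series(lengths, index=genes))


class TestGeneRelativeAbundance:
    def test_equal_counts_equal_lengths_split_evenly(self):
        ab = gene_relative_abundance(_counts([[5], [5]]), _genes([200, 200]))
        np.testing.assert_allclose(ab.values["s0"], [0.5, 0.5])

    def test_length_normalisation_hand_case(self):
        # counts (10, 20), lengths (100, 400): rates 0.1 and 0.05 -> 2/3, 1/3
        ab = gene_relative_abundance(_counts([[10], [20]]), _genes([100, 400]))
        np.testing.assert_allclose(ab.values["s0"], [2 / 3, 1 / 3], rtol=1e-12)

    def test_scaling_a_sample_leaves_abundance_unchanged(self):
        c1 = _counts([[10, 70], [20, 140], [5, 35]])
        ab = gene_relative_abundance(c1, _genes([150, 400, 900]))
        np.testing.assert_allclose(
            ab.values["s0"].to_numpy(), ab.values["s1"].to_numpy(), rtol=1e-12
        )

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(5)
        c = _counts(rng.integers(1, 100, size=(30, 6)))
        ab = gene_relative_abundance(c, _genes(rng.integers(100, 2000, 30).tolist()))
        np.testing.assert_allclose(ab.values.sum(axis=0), 1.0, atol=1e-9)
        assert ab.relative

    def test_all_zero_sample_names_the_sample(self):
        with pytest.raises(FormatError, match="s1"):
            gene_relative_abundance(_counts([[3, 0], [2, 0]]), _genes([100, 100]))

    def test_missing_length_is_an_error(self):
        with pytest.raises(FormatError, match="missing"):
            gene_relative_abundance(
                _counts([[3], [2]]), _genes([100], genes=["g0"])
            )


class TestAggregateByAnnotation:
    def test_ko_abundance_is_member_sum(self):
        ab = make_abundance([[0.1], [0.2], [0.7]])
        ann = AnnotationMap({"f0": {"K1"}, "f1": {"K1"}})
        out = aggregate_by_annotation(ab, ann)
        assert out.values.loc["K1", "s0"] == pytest.approx(0.3)

    def test_unannotated_gene_contributes_nowhere(self):
        ab = make_abundance([[0.4], [0.6]])
        out = aggregate_by_annotation(ab, AnnotationMap({"f0": {"K1"}}))
        assert list(out.values.index) == ["K1"]
        assert out.values["s0"].sum() < 1

    def test_multi_annotated_gene_counts_fully_in_each_term(self):
        ab = make_abundance([[0.4]])
        out = aggregate_by_annotation(ab, AnnotationMap({"f0": {"K1", "K2"}}))
        np.testing.assert_allclose(out.values["s0"], [0.4, 0.4])

    def test_split_multi_divides_abundance(self):
        ab = make_abundance([[0.4]])
        out = aggregate_by_annotation(
            ab, AnnotationMap({"f0": {"K1", "K2"}}), split_multi=True
        )
        np.testing.assert_allclose(out.values["s0"], [0.2, 0.2])

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(11)
        n_genes, n_samples = 100, 8
        x = rng.random((n_genes, n_samples))
        ab = make_abundance(x)
        kos = [f"K{k}" for k in range(12)]
        gene_to_terms = {
            f"f{i}": set(rng.choice(kos, size=rng.integers(1, 4), replace=False))
            for i in rng.choice(n_genes, size=80, replace=False)
        }
        out = aggregate_by_annotation(ab, AnnotationMap(gene_to_terms))
        for ko in out.feature_ids:  # independent double loop
            expect = np.zeros(n_samples)
            for g, terms in gene_to_terms.items():
                if ko in terms:
                    expect += x[int(g[1:])]
            np.testing.assert_allclose(out.values.loc[ko], expect, atol=1e-12)

    def test_empty_annotation_map_rejected(self):
        with pytest.raises(FormatError, match="empty"):
            aggregate_by_annotation(make_abundance([[1.0]]), AnnotationMap({}))


def _hits(rows):
    return GeneHits(
        pd.DataFrame(rows, columns=["gene_id", "lineage", "pct_identity", "pct_overlap"])
    )


class TestAggregateByTaxon:
    def test_single_species_collects_column_sums(self):
        ab = make_abundance([[0.3, 0.1], [0.7, 0.9]], relative=True)
        hits = _hits(
            [("f0", "k__B;s__X", 99.0, 95.0), ("f1", "k__B;s__X", 98.0, 96.0)]
        )
        out = aggregate_by_taxon(ab, hits, rank="species")
        assert list(out.values.index) == ["X"]
        np.testing.assert_allclose(out.values.loc["X"], [1.0, 1.0])

    def test_identity_at_threshold_is_unclassified(self):
        ab = make_abundance([[1.0]], relative=True)
        hits = _hits([("f0", "k__B;s__X", 94.9, 95.0)])
        out = aggregate_by_taxon(ab, hits, rank="species")
        assert list(out.values.index) == [UNCLASSIFIED]

    def test_exact_95_identity_is_not_qualifying(self):
        ab = make_abundance([[1.0]], relative=True)
        hits = _hits([("f0", "k__B;s__X", 95.0, 99.0)])
        out = aggregate_by_taxon(ab, hits, rank="species")
        assert list(out.values.index) == [UNCLASSIFIED]

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(23)
        n = 40
        x = rng.random((n, 5))
        x /= x.sum(axis=0)
        ab = make_abundance(x, relative=True)
        species = [f"Sp{k}" for k in range(4)]
        rows, truth = [], {}
        for i in range(n):
            sp = species[rng.integers(4)]
            ident = float(rng.uniform(90, 100))
            rows.append((f"f{i}", f"k__B;s__{sp}", ident, 95.0))
            truth[f"f{i}"] = sp if ident > 95 else UNCLASSIFIED
        out = aggregate_by_taxon(ab, _hits(rows), rank="species")
        for taxon in out.feature_ids:
            expect = np.zeros(5)
            for i in range(n):
                if truth[f"f{i}"] == taxon:
                    expect += x[i]
            np.testing.assert_allclose(out.values.loc[taxon], expect, atol=1e-12)
        np.testing.assert_allclose(out.values.sum(axis=0), 1.0, atol=1e-9)

    def test_unknown_rank_is_usage_error(self):
        ab = make_abundance([[1.0]], relative=True)
        with pytest.raises(ValueError, match="unknown rank"):
            aggregate_by_taxon(ab, _hits([("f0", "k__B", 99, 99)]), rank="tribe")
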