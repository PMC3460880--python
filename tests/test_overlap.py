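"""Phenotype gene-set construction and k-way overlap enumeration."""

from itertools import combinations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleioscan.config import PHENOTYPES
from pleioscan.overlap import (
    PhenotypeGeneSet,
    build_phenotype_gene_sets,
    collapse_regions,
    enumerate_overlaps,
    gene_pleiotropy_report,
    overlaps_to_frame,
    summarize_counts,
)


def make_sets(**genes_by_phen):
    sets = {p: PhenotypeGeneSet(p, "pooled") for p in PHENOTYPES}
    for p, genes in genes_by_phen.items():
        sets[p].genes = set(genes)
        sets[p].provenance = {g: [("S", "rs1")] for g in genes}
    return sets


def gene_table(rows):
    return pd.DataFrame(
        rows,
        columns=["study_id", "phenotype", "gene", "snp_id", "ancestry", "relation", "weight"],
    )


class TestBuildSets:
    def test_union_across_studies(self):
        rows = gene_table(
            [
                ("S1", "CAD", "A", "rs1", "european", "within", 1),
                ("S1", "CAD", "B", "rs2", "european", "within", 1),
                ("S2", "CAD", "B", "rs3", "european", "within", 1),
                ("S2", "CAD", "C", "rs4", "european", "within", 1),
            ]
        )
        sets = build_phenotype_gene_sets(rows)
        assert sets["CAD"].genes == {"A", "B", "C"}
        assert len(sets["CAD"].provenance["B"]) == 2

    def test_stratum_with_no_studies_gives_empty_set(self):
        rows = gene_table([("S1", "Obesity", "A", "rs1", "european", "within", 1)])
        sets = build_phenotype_gene_sets(rows, stratum="african")
        assert sets["Obesity"].genes == set()

    def test_empty_input_all_six_sets_empty(self):
        sets = build_phenotype_gene_sets(gene_table([]))
        assert set(sets) == set(PHENOTYPES)
        assert all(s.genes == set() for s in sets.values())

    def test_stratified_sets_subset_of_pooled(self):
        rows = gene_table(
            [
                ("S1", "BP", "A", "rs1", "european", "within", 1),
                ("S2", "BP", "B", "rs2", "african", "within", 1),
                ("S3", "CKD", "C", "rs3", "european", "within", 1),
            ]
        )
        pooled = build_phenotype_gene_sets(rows, "pooled")
        for stratum in ("european", "african"):
            strat = build_phenotype_gene_sets(rows, stratum)
            for p in PHENOTYPES:
                assert strat[p].genes <= pooled[p].genes


class TestEnumerateOverlaps:
    def test_simple_pair(self):
        sets = make_sets(BP={"g1", "g2"}, CAD={"g2", "g3"})
        out = enumerate_overlaps(sets)
        assert len(out) == 1
        assert out[0].phenotypes == ("BP", "CAD")
        assert out[0].shared_genes == {"g2"}
        assert out[0].list_sizes == (2, 2)

    def test_gene_in_four_sets_appears_in_eleven_combinations(self):
        sets = make_sets(BP={"g"}, CAD={"g"}, CKD={"g"}, Lipids={"g"})
        out = enumerate_overlaps(sets)
        assert len(out) == 11  # C(4,2)+C(4,3)+C(4,4)
        report = gene_pleiotropy_report(sets)
        assert report.iloc[0]["n_phenotypes"] == 4

    def test_disjoint_sets_no_overlaps(self):
        sets = make_sets(BP={"a"}, CAD={"b"}, T2D={"c"})
        assert enumerate_overlaps(sets) == []

    def test_k_min_validation(self):
        with pytest.raises(ValueError):
            enumerate_overlaps(make_sets(), k_min=1)

    @given(
        st.dictionaries(
            st.sampled_from(PHENOTYPES),
            st.sets(st.integers(0, 15), max_size=8),
            min_size=2,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_subset_closure(self, raw):
        """Any sub-combination's intersection contains the parent's."""
        sets = make_sets(**{p: {f"g{i}" for i in gs} for p, gs in raw.items()})
        results = {o.phenotypes: o.shared_genes for o in enumerate_overlaps(sets)}
        for combo, shared in results.items():
            for k in range(2, len(combo)):
                for sub in combinations(combo, k):
                    assert shared <= results.get(sub, set())

    @given(
        st.dictionaries(
            st.sampled_from(PHENOTYPES),
            st.sets(st.integers(0, 20), max_size=10),
            min_size=2,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_shared_count_matches_membership_tally(self, raw):
        sets = make_sets(**{p: {f"g{i}" for i in gs} for p, gs in raw.items()})
        report = gene_pleiotropy_report(sets)
        all_genes = set().union(*(s.genes for s in sets.values()))
        expected = sum(
            1 for g in all_genes if sum(g in s.genes for s in sets.values()) >= 2
        )
        assert len(report) == expected


class TestSummarizeCounts:
    def test_counts_from_synthetic_construction(self):
        records = pd.DataFrame(
            {
                "study_id": ["S1", "S1", "S2", "S3"],
                "phenotype": ["CAD", "CAD", "CAD", "BP"],
                "snp_id": ["rs1", "rs2", "rs3", "rs4"],
                "ancestry": ["european", "european", "african", "european"],
            }
        )
        genes = gene_table(
            [
                ("S1", "CAD", "A", "rs1", "european", "within", 1),
                ("S1", "CAD", "B", "rs2", "european", "within", 1),
                ("S2", "CAD", "C", "rs3", "african", "within", 1),
                ("S3", "BP", "A", "rs4", "european", "within", 1),
            ]
        )
        table = summarize_counts(records, genes)
        cad = table[table["phenotype"] == "CAD"].iloc[0]
        assert (cad["n_studies_all"], cad["n_snps_all"], cad["n_genes_all"]) == (2, 3, 3)
        assert cad["n_genes_african"] == 1
        shared = table[table["phenotype"] == "Shared by 2+ phenotypes"].iloc[0]
        assert shared["n_genes_all"] == 1  # gene A in CAD and BP

    def test_no_shared_genes_row_zero(self):
        genes = gene_table([("S1", "CAD", "A", "rs1", "european", "within", 1)])
        records = pd.DataFrame(
            {
                "study_id": ["S1"],
                "phenotype": ["CAD"],
                "snp_id": ["rs1"],
                "ancestry": ["european"],
            }
        )
        table = summarize_counts(records, genes)
        assert table[table["phenotype"] == "Shared by 2+ phenotypes"].iloc[0][
            "n_genes_all"
        ] == 0

    def test_gene_in_three_phenotypes_counted_once(self):
        genes = gene_table(
            [
                ("S1", "CAD", "A", "rs1", "european", "within", 1),
                ("S2", "BP", "A", "rs2", "european", "within", 1),
                ("S3", "CKD", "A", "rs3", "european", "within", 1),
            ]
        )
        records = pd.DataFrame(
            {
                "study_id": ["S1", "S2", "S3"],
                "phenotype": ["CAD", "BP", "CKD"],
                "snp_id": ["rs1", "rs2", "rs3"],
                "ancestry": ["european"] * 3,
            }
        )
        table = summarize_counts(records, genes)
        assert table[table["phenotype"] == "Shared by 2+ phenotypes"].iloc[0][
            "n_genes_all"
        ] == 1


class TestRegionCollapse:
    def test_flank_pair_merged_into_region(self):
        rows = gene_table(
            [
                ("S1", "Lipids", "APOB", "rs1", "european", "left_flank", 1),
                ("S1", "Lipids", "KLHL29", "rs1", "european", "right_flank", 1),
                ("S1", "Lipids", "GCKR", "rs2", "european", "within", 1),
            ]
        )
        out = collapse_regions(rows)
        assert set(out["gene"]) == {"APOB|KLHL29", "GCKR"}

    def test_overlaps_to_frame_columns(self):
        sets = make_sets(BP={"g"}, CAD={"g"})
        df = overlaps_to_frame(enumerate_overlaps(sets))
        assert df.iloc[0]["phenotypes"] == "BP;CAD"
        assert df.iloc[0]["k_observed"] == 1
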