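import textwrap

import pytest

from pleioscan.gene_mapping import GeneModel, GenomeIndex

CATALOG_HEADER = (
    "PUBMEDID\tDISEASE/TRAIT\tSNPS\tCHR_ID\tCHR_POS\tP-VALUE\t"
    "REPORTED GENE(S)\tINITIAL SAMPLE DESCRIPTION\tPLATFORM [SNPS PASSING QC]"
)


def make_catalog(tmp_path, rows, name="catalog.tsv"):
    """Write a small catalog TSV from (trait, snp, chrom, pos, p, genes,
    ancestry, platform) tuples; study id defaults to row index."""
    lines = [CATALOG_HEADER]
    for i, r in enumerate(rows):
        study = r.get("study", f"2000{i:02d}")
        lines.append(
            "\t".join(
                [
                    study,
                    r.get("trait", "LDL cholesterol"),
                    r.get("snp", f"rs{i + 1}"),
                    r.get("chrom", "1"),
                    str(r.get("pos", 500)),
                    str(r.get("p", 1e-8)),
                    r.get("genes", ""),
                    r.get("ancestry", "European ancestry individuals"),
                    r.get("platform", "Illumina [550,000]"),
                ]
            )
        )
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def catalog_factory(tmp_path):
    return lambda rows, name="catalog.tsv": make_catalog(tmp_path, rows, name)


@pytest.fixture
def small_genes():
    """Two chromosomes: A[100,900], B[5000,6000] on chr1; C[100,200] on chr2."""
    return [
        GeneModel("A", "1", 100, 900),
        GeneModel("B", "1", 5000, 6000),
        GeneModel("C", "2", 100, 200),
    ]


@pytest.fixture
def small_index(small_genes):
    return GenomeIndex(small_genes)


@pytest.fixture
def bed_file(tmp_path):
    """BED (0-based half-open) version of the small annotation."""
    path = tmp_path / "genes.bed"
    path.write_text(
        textwrap.dedent(
            """\
            1\t99\t900\tA
            1\t4999\t6000\tB
            2\t99\t200\tC
            """
        )
    )
    return path
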