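"""Per-phenotype gene sets and k-way overlap enumeration.

A gene is *pleiotropic* here when it appears in the positional gene sets of
two or more phenotype categories.  Overlaps are enumerated for every
phenotype combination of size >= 2 with a non-empty intersection — all
combinations, not only maximal ones, since a 4-way shared gene also
participates in each nested 3-way and 2-way combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .config import PHENOTYPES


@dataclass
class PhenotypeGeneSet:
    """Deduplicated positional genes attributed to one phenotype category."""

    phenotype: str
    stratum: str
    genes: set[str] = field(default_factory=set)
    #: gene -> list of (study_id, snp_id) supporting its inclusion
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class OverlapResult:
    """One phenotype combination and the genes common to all its members."""

    phenotypes: tuple[str, ...]
    shared_genes: set[str]
    list_sizes: tuple[int, ...]
    pool_size: int

    @property
    def k_observed(self) -> int:
        return len(self.shared_genes)

    @property
    def k(self) -> int:
        return len(self.phenotypes)


def build_phenotype_gene_sets(
    gene_rows: pd.DataFrame, stratum: str = "pooled"
) -> dict[str, PhenotypeGeneSet]:
    """Union of deduplicated genes per phenotype within an ancestry stratum.

    ``stratum='pooled'`` uses every record; ``'european'`` / ``'african'``
    restrict to records from studies of that discovery ancestry.  Phenotypes
    with no qualifying records get empty sets (they still appear, so that
    downstream code sees all six categories).
    """
    sets = {p: PhenotypeGeneSet(p, stratum) for p in PHENOTYPES}
    if gene_rows.empty:
        return sets
    rows = gene_rows
    if stratum != "pooled":
        rows = rows[rows["ancestry"] == stratum]
    for rec in rows.itertuples(index=False):
        if rec.phenotype not in sets:
            continue
        ps = sets[rec.phenotype]
        ps.genes.add(rec.gene)
        ps.provenance.setdefault(rec.gene, []).append((rec.study_id, rec.snp_id))
    return sets


def enumerate_overlaps(
    sets: dict[str, PhenotypeGeneSet],
    k_min: int = 2,
    pool_size: int | None = None,
) -> list[OverlapResult]:
    """All phenotype combinations of size >= k_min with non-empty intersection.

    Results are ordered by combination size then phenotype order, so output
    is deterministic.  ``pool_size`` defaults to the number of distinct genes
    across all sets (the ingested non-MHC positional gene pool).
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    labels = [p for p in PHENOTYPES if p in sets]
    labels += [p for p in sets if p not in PHENOTYPES]
    if pool_size is None:
        pool_size = len(set().union(*(sets[p].genes for p in labels))) if labels else 0
    out: list[OverlapResult] = []
    for k in range(k_min, len(labels) + 1):
        for combo in combinations(labels, k):
            shared = set.intersection(*(sets[p].genes for p in combo))
            if shared:
                out.append(
                    OverlapResult(
                        phenotypes=combo,
                        shared_genes=shared,
                        list_sizes=tuple(sets[p].size for p in combo),
                        pool_size=pool_size,
                    )
                )
    return out


def gene_pleiotropy_report(sets: dict[str, PhenotypeGeneSet]) -> pd.DataFrame:
    """Per-gene maximal pleiotropy: the full set of phenotypes carrying it.

    Only genes present in >= 2 phenotype sets are listed.
    """
    membership: dict[str, list[str]] = {}
    for p in PHENOTYPES:
        if p not in sets:
            continue
        for g in sets[p].genes:
            membership.setdefault(g, []).append(p)
    rows = [
        {"gene": g, "n_phenotypes": len(ps), "phenotypes": ";".join(ps)}
        for g, ps in sorted(membership.items())
        if len(ps) >= 2
    ]
    return pd.DataFrame(rows, columns=["gene", "n_phenotypes", "phenotypes"])


def collapse_regions(gene_rows: pd.DataFrame) -> pd.DataFrame:
    """Optional region-level view: merge the two flanking genes of one SNP.

    An intergenic signal assigned to both flanking genes (an APOB/KLHL29-like
    pair) counts as two genes under the catalog's positional definition; this
    toggle instead replaces each left/right flank pair arising from a single
    SNP with one pseudo-gene named ``LEFT|RIGHT`` so overlaps can be counted
    per genomic region.
    """
    if gene_rows.empty:
        return gene_rows.copy()
    df = gene_rows.copy()
    flank = df[df["relation"].isin(["left_flank", "right_flank"])]
    key_cols = ["study_id", "phenotype", "snp_id"]
    region_name = (
        flank.sort_values("relation")  # left_flank sorts before right_flank
        .groupby(key_cols)["gene"]
        .agg(lambda genes: "|".join(genes))
    )
    df = df.merge(region_name.rename("region"), on=key_cols, how="left")
    df["gene"] = df["region"].where(df["region"].notna(), df["gene"])
    df = df.drop(columns=["region"]).drop_duplicates(["study_id", "phenotype", "gene", "snp_id"])
    return df.reset_index(drop=True)


def summarize_counts(
    records: pd.DataFrame, gene_rows: pd.DataFrame
) -> pd.DataFrame:
    """Per-phenotype study / SNP / gene counts by ancestry stratum.

    Mirrors the layout of a catalog summary table: one row per phenotype,
    one row counting genes shared by >= 2 phenotypes, and a totals row;
    columns give counts for the pooled, European-only and African-only
    strata.  Counts are computed from the normalized association records
    (studies, SNPs) and the deduplicated gene table (genes).
    """
    strata = [("all", None), ("european", "european"), ("african", "african")]
    rows = []
    assigned = records[records["phenotype"].notna()] if not records.empty else records
    for phen in PHENOTYPES:
        row: dict[str, object] = {"phenotype": phen}
        for label, anc in strata:
            recs = assigned[assigned["phenotype"] == phen] if not assigned.empty else assigned
            genes = (
                gene_rows[gene_rows["phenotype"] == phen] if not gene_rows.empty else gene_rows
            )
            if anc is not None and not recs.empty:
                recs = recs[recs["ancestry"] == anc]
            if anc is not None and not genes.empty:
                genes = genes[genes["ancestry"] == anc]
            row[f"n_studies_{label}"] = 0 if recs.empty else recs["study_id"].nunique()
            row[f"n_snps_{label}"] = 0 if recs.empty else recs["snp_id"].nunique()
            row[f"n_genes_{label}"] = 0 if genes.empty else genes["gene"].nunique()
        rows.append(row)

    shared_row: dict[str, object] = {"phenotype": "Shared by 2+ phenotypes"}
    total_row: dict[str, object] = {"phenotype": "Total"}
    for label, anc in strata:
        genes = gene_rows
        recs = assigned
        if anc is not None and not genes.empty:
            genes = genes[genes["ancestry"] == anc]
        if anc is not None and not recs.empty:
            recs = recs[recs["ancestry"] == anc]
        if genes.empty:
            n_shared, n_genes = 0, 0
        else:
            per_gene = genes.groupby("gene")["phenotype"].nunique()
            n_shared = int((per_gene >= 2).sum())
            n_genes = genes["gene"].nunique()
        shared_row[f"n_studies_{label}"] = (
            0
            if genes.empty
            else genes[genes["gene"].isin(per_gene[per_gene >= 2].index)]["study_id"].nunique()
        )
        shared_row[f"n_snps_{label}"] = (
            0
            if genes.empty
            else genes[genes["gene"].isin(per_gene[per_gene >= 2].index)]["snp_id"].nunique()
        )
        shared_row[f"n_genes_{label}"] = n_shared
        total_row[f"n_studies_{label}"] = 0 if recs.empty else recs["study_id"].nunique()
        total_row[f"n_snps_{label}"] = 0 if recs.empty else recs["snp_id"].nunique()
        total_row[f"n_genes_{label}"] = n_genes
    rows.append(shared_row)
    rows.append(total_row)
    return pd.DataFrame(rows)


def overlaps_to_frame(overlaps: list[OverlapResult]) -> pd.DataFrame:
    """Serialize overlap results to a flat table (TSV-ready)."""
    rows = [
        {
            "phenotypes": ";".join(o.phenotypes),
            "k": o.k,
            "k_observed": o.k_observed,
            "shared_genes": ";".join(sorted(o.shared_genes)),
            "list_sizes": ";".join(map(str, o.list_sizes)),
            "pool_size": o.pool_size,
        }
        for o in overlaps
    ]
    return pd.DataFrame(
        rows,
        columns=["phenotypes", "k", "k_observed", "shared_genes", "list_sizes", "pool_size"],
    )
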