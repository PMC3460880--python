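"""Positional SNP-to-gene assignment with MHC exclusion and per-study dedup.

The assignment rule is the GWAS catalog's positional-gene definition:

* a SNP falling inside a gene is assigned that gene (all genes, if several
  overlapping genes contain it);
* an intergenic SNP is assigned both the nearest gene ending before it
  (left flank) and the nearest gene starting after it (right flank),
  irrespective of distance.

Left/right are defined by coordinate order; strand is ignored.  Coordinates
are 1-based inclusive internally (catalog convention); BED input is converted
from 0-based half-open on read.

Genes inside the MHC/HLA region are excluded from pleiotropy counting: the
region's extreme polymorphism and gene density would otherwise dominate any
overlap signal.  Where multiple SNPs in one study map to the same gene for
the same phenotype, only one (study, phenotype, gene) record is kept, but the
pre-dedup multiplicity is preserved as a weight for the weighted null.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A named gene interval, 1-based inclusive."""

    symbol: str
    chrom: str
    start: int
    end: int
    mhc_flag: bool = False

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.start > self.end:
            raise ValueError(f"gene {self.symbol}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class GeneAssignment:
    gene: str
    snp_id: str
    relation: str  # within | left_flank | right_flank
    distance_bp: int

    def __post_init__(self) -> None:
        if (self.relation == "within") != (self.distance_bp == 0):
            raise ValueError("relation 'within' iff distance_bp == 0")


# --------------------------------------------------------------------------
# annotation input

def read_annotation(path) -> list[GeneModel]:
    """Read gene models from BED (4+ columns) or GFF3 (``gene`` features).

    BED start coordinates (0-based half-open) are shifted to the 1-based
    inclusive convention used internally.
    """
    path = str(path)
    if path.endswith((".gff3", ".gff")):
        return _read_gff3(path)
    return _read_bed(path)


def _read_bed(path: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError("BED annotation needs >=4 columns (chrom,start,end,name)")
    genes = [
        GeneModel(
            symbol=name,
            chrom=str(chrom).removeprefix("chr"),
            start=int(start) + 1,  # 0-based half-open -> 1-based inclusive
            end=int(end),
        )
        for chrom, start, end, name in zip(df[0], df[1], df[2], df[3])
    ]
    logger.info("read %d gene models from BED %s (coords shifted +1)", len(genes), path)
    _check_unique_symbols(genes)
    return genes


def _read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="warning"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [feat.id])[0]
        genes.append(
            GeneModel(
                symbol=name,
                chrom=str(feat.seqid).removeprefix("chr"),
                start=feat.start,
                end=feat.end,
            )
        )
    _check_unique_symbols(genes)
    return genes


def _check_unique_symbols(genes: list[GeneModel]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.symbol in seen:
            raise ValueError(f"duplicate gene symbol in annotation: {g.symbol!r}")
        seen.add(g.symbol)


def flag_mhc_genes(
    genes: list[GeneModel], mhc_region: tuple[str, int, int]
) -> list[GeneModel]:
    """Return gene models with ``mhc_flag`` set where they overlap the region."""
    chrom, lo, hi = mhc_region
    chrom = str(chrom).removeprefix("chr")
    out = []
    for g in genes:
        hit = g.chrom == chrom and g.start <= hi and g.end >= lo
        out.append(GeneModel(g.symbol, g.chrom, g.start, g.end, mhc_flag=hit) if hit != g.mhc_flag else g)
    return out


# --------------------------------------------------------------------------
# positional assignment

class GenomeIndex:
    """Per-chromosome interval index over gene models.

    Containment queries go through an interval tree; flank queries use
    start/end-sorted arrays so that "nearest gene ending before pos" and
    "nearest gene starting after pos" are O(log n) bisections.
    """

    def __init__(self, genes: list[GeneModel]):
        self.genes = {g.symbol: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        self._by_start: dict[str, list[tuple[int, str]]] = {}
        self._by_end: dict[str, list[tuple[int, str]]] = {}
        per_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            per_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in per_chrom.items():
            # end+1 because IntervalTree intervals are half-open
            self._trees[chrom] = IntervalTree.from_tuples(
                (g.start, g.end + 1, g.symbol) for g in gs
            )
            self._by_start[chrom] = sorted((g.start, g.symbol) for g in gs)
            self._by_end[chrom] = sorted((g.end, g.symbol) for g in gs)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def assign(self, chrom: str | None, pos: int | None, snp_id: str = "") -> list[GeneAssignment]:
        """Positional assignments for one SNP (see module docstring rules)."""
        if chrom is None or pos is None:
            return []
        chrom = str(chrom).removeprefix("chr")
        if chrom not in self._trees:
            logger.warning("SNP %s on unannotated chromosome %r", snp_id or "?", chrom)
            return []
        within = sorted(iv.data for iv in self._trees[chrom][pos])
        if within:
            return [GeneAssignment(sym, snp_id, "within", 0) for sym in within]
        out: list[GeneAssignment] = []
        ends = self._by_end[chrom]
        i = bisect.bisect_left(ends, (pos, "")) - 1  # rightmost end < pos
        if i >= 0:
            end, sym = ends[i]
            out.append(GeneAssignment(sym, snp_id, "left_flank", pos - end))
        starts = self._by_start[chrom]
        j = bisect.bisect_right(starts, (pos, "￿"))  # leftmost start > pos
        if j < len(starts):
            start, sym = starts[j]
            out.append(GeneAssignment(sym, snp_id, "right_flank", start - pos))
        return out


def assign_positional_genes(
    chrom: str | None, pos: int | None, genes, snp_id: str = ""
) -> list[GeneAssignment]:
    """Convenience wrapper: build (or reuse) an index and assign one SNP."""
    index = genes if isinstance(genes, GenomeIndex) else GenomeIndex(list(genes))
    return index.assign(chrom, pos, snp_id)


def exclude_mhc(
    assignments: list[GeneAssignment],
    index: GenomeIndex,
    mhc_region: tuple[str, int, int],
) -> tuple[list[GeneAssignment], int]:
    """Drop assignments to genes overlapping the MHC interval or flagged MHC.

    Returns the filtered list and the number removed.
    """
    chrom, lo, hi = mhc_region
    chrom = str(chrom).removeprefix("chr")
    kept = []
    removed = 0
    for a in assignments:
        g = index.genes.get(a.gene)
        in_region = (
            g is not None and (g.mhc_flag or (g.chrom == chrom and g.start <= hi and g.end >= lo))
        )
        if in_region:
            removed += 1
        else:
            kept.append(a)
    if removed:
        logger.info("excluded %d MHC-region gene assignments", removed)
    return kept, removed


# --------------------------------------------------------------------------
# catalog-level mapping

GENE_TABLE_COLUMNS = [
    "study_id",
    "phenotype",
    "gene",
    "snp_id",
    "ancestry",
    "relation",
    "weight",
]


def map_catalog(
    records: pd.DataFrame,
    index: GenomeIndex,
    mhc_region: tuple[str, int, int],
    mode: str = "positional",
) -> pd.DataFrame:
    """Map normalized association rows to per-SNP gene rows.

    ``mode='positional'`` applies the positional rule; ``mode='reported'``
    uses the author-reported gene symbols instead (rows without reported
    genes are skipped).  MHC genes are excluded in both modes.  The result
    is NOT yet deduplicated — see :func:`dedup_per_study_trait`.
    """
    if mode not in ("positional", "reported"):
        raise ValueError(f"unknown mapping mode {mode!r}")
    chrom_mhc, lo, hi = mhc_region
    chrom_mhc = str(chrom_mhc).removeprefix("chr")

    def _is_mhc(sym: str) -> bool:
        g = index.genes.get(sym)
        return g is not None and (
            g.mhc_flag or (g.chrom == chrom_mhc and g.start <= hi and g.end >= lo)
        )

    rows = []
    n_unmapped = 0
    for rec in records.itertuples(index=False):
        if rec.phenotype is None:
            continue
        if mode == "reported":
            for sym in rec.reported_genes:
                if not _is_mhc(sym):
                    rows.append((rec.study_id, rec.phenotype, sym, rec.snp_id, rec.ancestry, "reported"))
            continue
        assigns = index.assign(rec.chrom, rec.pos, rec.snp_id)
        if not assigns:
            n_unmapped += 1
            continue
        for a in assigns:
            if not _is_mhc(a.gene):
                rows.append((rec.study_id, rec.phenotype, a.gene, rec.snp_id, rec.ancestry, a.relation))
    if n_unmapped:
        logger.info("%d records yielded no positional assignment", n_unmapped)
    return pd.DataFrame(
        rows, columns=["study_id", "phenotype", "gene", "snp_id", "ancestry", "relation"]
    )


def dedup_per_study_trait(gene_rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse to unique (study, phenotype, gene) records.

    The number of distinct SNPs that mapped to the gene within the group is
    kept as ``weight`` so the weighted permutation null can account for
    multiplicity.  Idempotent: re-running on its own output is a no-op.
    """
    if gene_rows.empty:
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)
    # on already-deduplicated input the weight column is summed (each group
    # is a single row), so the operation is idempotent
    weight_agg = (
        ("weight", "sum") if "weight" in gene_rows.columns else ("snp_id", "nunique")
    )
    grouped = (
        gene_rows.groupby(["study_id", "phenotype", "gene"], sort=False)
        .agg(
            snp_id=("snp_id", "first"),
            ancestry=("ancestry", "first"),
            relation=("relation", "first"),
            weight=weight_agg,
        )
        .reset_index()
    )
    return grouped[GENE_TABLE_COLUMNS]
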